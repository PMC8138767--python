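"""Per-residue NMR titration intensity-change mapping.

Binding of a partner to a disordered region in intermediate exchange
broadens the resonances of contacting residues, so the per-residue
attenuation statistic

    percent_change = 1 - I_bound / I_unbound

(after normalising each dataset onto a common scale) localises the binding
footprint along the sequence. This module reads peak lists (Sparky-style or
generic CSV), computes the attenuation profile, bins it with the
light-to-dark threshold schemes used for structure surface colouring,
detects contiguous binding motifs, and exports residue attribute files for
structure viewers.

Conventions:

* residue numbers are 1-based in the native full-length protein sequence
  (e.g. Pdx1 204-283, SPOP 28-166); expression-tag artifacts are excluded,
* residues missing from either dataset (peak overlap, unassigned, omitted)
  carry no attenuation value and are binned with the darkest class, the
  same convention used for surface colouring,
* changes are stored as fractions in [0, 1] internally and displayed on the
  0-100 percent scale.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakListError",
    "ResidueIntensityProfile",
    "BinScheme",
    "BindingRegion",
    "BIN_SCHEMES",
    "SBM1_4BIN",
    "SBM2_3BIN",
    "read_peak_list",
    "write_sparky_list",
    "compute_intensity_change",
    "bin_changes",
    "detect_binding_regions",
    "export_attributes",
    "read_attributes",
    "write_profile_csv",
]


class PeakListError(ValueError):
    """Unreadable or inconsistent peak list."""


# assignment tokens like "G220N-H", "V229CA-HA", "S273N"; first integer is
# the residue number
_ASSIGNMENT_RE = re.compile(r"^[A-Za-z]{0,3}(\d+)")


def _parse_assignment(token: str) -> int | None:
    m = _ASSIGNMENT_RE.match(token.strip())
    return int(m.group(1)) if m else None


def read_peak_list(path, dialect: str | None = None) -> pd.DataFrame:
    """Read a peak list into a table with columns ``residue``, ``intensity``.

    ``dialect`` is ``"sparky_list"`` (whitespace-delimited: assignment,
    shift columns..., intensity last) or ``"generic_csv"`` (columns
    ``residue,intensity``); ``None`` auto-detects from the file content.
    Unparseable rows are skipped with a warning; duplicate residues are an
    error because the attenuation statistic needs one intensity per residue.
    """
    path = Path(path)
    text = path.read_text()
    if dialect is None:
        dialect = "generic_csv" if "residue" in text.splitlines()[0].lower() else "sparky_list"
    if dialect == "generic_csv":
        df = pd.read_csv(path)
        if "residue" not in df.columns or "intensity" not in df.columns:
            raise PeakListError(f"{path}: generic_csv requires 'residue' and 'intensity' columns")
        records = list(zip(df["residue"].astype(int), df["intensity"].astype(float)))
    elif dialect == "sparky_list":
        records = []
        n_skipped = 0
        for line in text.splitlines():
            line = line.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            fields = line.split()
            residue = _parse_assignment(fields[0])
            if residue is None or len(fields) < 2:
                n_skipped += 1
                continue
            try:
                intensity = float(fields[-1])
            except ValueError:
                n_skipped += 1
                continue
            records.append((residue, intensity))
        if n_skipped:
            warnings.warn(
                f"{path}: skipped {n_skipped} unparseable peak-list row(s)",
                RuntimeWarning,
                stacklevel=2,
            )
    else:
        raise PeakListError(f"unknown peak-list dialect {dialect!r}")
    if not records:
        raise PeakListError(f"{path}: no parseable rows")
    residues = [r for r, _ in records]
    dupes = sorted({r for r in residues if residues.count(r) > 1})
    if dupes:
        raise PeakListError(f"{path}: duplicate assignment(s) for residue(s) {dupes}")
    out = pd.DataFrame(records, columns=["residue", "intensity"])
    return out.sort_values("residue").reset_index(drop=True)


_ONE_LETTER = "X"  # residue type is not tracked; peak lists key on number only


def write_sparky_list(table: pd.DataFrame, path, sequence: dict[int, str] | None = None) -> None:
    """Write a ``residue,intensity`` table as a Sparky-style peak list.

    Assignment tokens are ``<aa><residue>N-H``; ``sequence`` optionally maps
    residue numbers to one-letter codes (default ``X``). Shift columns are
    placeholders: only the assignment and the trailing intensity column are
    meaningful to :func:`read_peak_list`.
    """
    path = Path(path)
    lines = ["      Assignment         w1         w2   Data Height"]
    for _, row in table.sort_values("residue").iterrows():
        res = int(row["residue"])
        aa = (sequence or {}).get(res, _ONE_LETTER)
        lines.append(f"{aa}{res}N-H\t120.000\t8.000\t{row['intensity']:.6e}")
    path.write_text("\n".join(lines) + "\n")


@dataclass
class ResidueIntensityProfile:
    """Per-residue apo/bound intensities and attenuation over a sequence window.

    ``table`` is indexed by residue number with columns ``intensity_unbound``,
    ``intensity_bound`` (normalised), ``percent_change`` (fraction; NaN where
    missing), ``missing`` (bool) and ``missing_reason``
    ({"", "overlap", "unassigned", "omitted"}).
    """

    table: pd.DataFrame
    normalization: str = "least_perturbed_median"

    def __post_init__(self) -> None:
        idx = self.table.index.to_numpy()
        if len(idx) and not np.all(np.diff(idx) > 0):
            raise PeakListError("residue numbers must be strictly increasing")

    @property
    def residues(self) -> np.ndarray:
        return self.table.index.to_numpy()

    def scored(self) -> pd.DataFrame:
        """Rows with a defined percent_change."""
        return self.table[~self.table["missing"]]


_NORMALIZERS = ("least_perturbed_median", "total", "max")


def compute_intensity_change(
    apo: pd.DataFrame,
    bound: pd.DataFrame,
    normalization: str = "least_perturbed_median",
    min_common: int = 10,
    least_perturbed_fraction: float = 0.2,
) -> ResidueIntensityProfile:
    """Attenuation profile 1 - I_bound/I_unbound from apo and bound peak lists.

    Each dataset is first placed on a common scale. The default statistic
    rescales both datasets so that the median intensity over the 20% of
    shared residues whose raw bound/apo ratio is closest to 1 (the least
    perturbed residues) equals 1; this keeps the binding signal itself from
    biasing the scale. ``"total"`` (sum of shared intensities) and ``"max"``
    (largest shared peak) are simpler alternatives.

    Residues present in only one table are flagged missing with reason
    ``"omitted"``. Negative changes (intensity gain) are retained.
    """
    if normalization not in _NORMALIZERS:
        raise PeakListError(f"unknown normalization {normalization!r}; one of {_NORMALIZERS}")
    apo = apo.set_index("residue") if "residue" in apo.columns else apo
    bound = bound.set_index("residue") if "residue" in bound.columns else bound
    common = apo.index.intersection(bound.index)
    if len(common) < min_common:
        raise PeakListError(
            f"only {len(common)} residues shared between datasets; need >= {min_common}"
        )
    i_u = apo.loc[common, "intensity"].to_numpy(float)
    i_b = bound.loc[common, "intensity"].to_numpy(float)
    if np.any(i_u <= 0):
        raise PeakListError("apo intensities must be positive for ratio computation")

    if normalization == "least_perturbed_median":
        # least-perturbed residues = log-ratios closest to the median log-ratio;
        # the median tracks any global gain difference, so the selection (and
        # hence the profile) is invariant under per-dataset rescaling
        log_ratio = np.log(np.maximum(i_b / i_u, 1e-12))
        n_ref = max(int(np.ceil(least_perturbed_fraction * len(common))), 3)
        ref = np.argsort(np.abs(log_ratio - np.median(log_ratio)), kind="stable")[:n_ref]
        scale_u = np.median(i_u[ref])
        scale_b = np.median(i_b[ref])
    elif normalization == "total":
        scale_u, scale_b = i_u.sum(), i_b.sum()
    else:  # max
        scale_u, scale_b = i_u.max(), i_b.max()
    if scale_u == 0 or scale_b == 0:
        raise PeakListError("normalization statistic is zero")

    all_res = sorted(set(apo.index) | set(bound.index))
    rows = []
    for res in all_res:
        in_apo, in_bound = res in apo.index, res in bound.index
        iu = float(apo.loc[res, "intensity"]) / scale_u if in_apo else np.nan
        ib = float(bound.loc[res, "intensity"]) / scale_b if in_bound else np.nan
        missing = not (in_apo and in_bound)
        change = np.nan if missing else 1.0 - ib / iu
        rows.append(
            {
                "intensity_unbound": iu,
                "intensity_bound": ib,
                "percent_change": change,
                "missing": missing,
                "missing_reason": "omitted" if missing else "",
            }
        )
    table = pd.DataFrame(rows, index=pd.Index(all_res, name="residue"))
    return ResidueIntensityProfile(table=table, normalization=normalization)


@dataclass(frozen=True)
class BinScheme:
    """Ordered attenuation bins on the 0-100 percent scale.

    ``thresholds`` are the descending interior bin edges; label i covers the
    lower-exclusive/upper-inclusive interval (thresholds[i], thresholds[i-1]]
    with the first label open above and the last a catch-all below. Labels
    run light (strongest attenuation) to dark; ``rank`` 0 is lightest.
    Missing residues are assigned the darkest (last) bin, matching the
    surface-colouring convention for overlapped/unassigned resonances.
    """

    name: str
    thresholds: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.thresholds) + 1:
            raise ValueError("need one more label than thresholds")
        if list(self.thresholds) != sorted(self.thresholds, reverse=True):
            raise ValueError("thresholds must be strictly descending")

    @property
    def darkest(self) -> str:
        return self.labels[-1]

    def rank(self, label: str) -> int:
        return self.labels.index(label)

    def assign(self, change_fraction: float) -> str:
        """Bin label for an attenuation given as a fraction (0-1 scale)."""
        percent = 100.0 * change_fraction
        for i, t in enumerate(self.thresholds):
            if percent > t:
                return self.labels[i]
        return self.labels[-1]


SBM1_4BIN = BinScheme(
    name="sbm1_4bin",
    thresholds=(90.0, 80.0, 70.0),
    labels=(">90", "80 to 90", "70 to 80", "<70"),
)
SBM2_3BIN = BinScheme(
    name="sbm2_3bin",
    thresholds=(70.0, 40.0),
    labels=(">70", "40 to 70", "<40"),
)
BIN_SCHEMES: dict[str, BinScheme] = {s.name: s for s in (SBM1_4BIN, SBM2_3BIN)}


def bin_changes(profile: ResidueIntensityProfile, scheme: BinScheme) -> pd.DataFrame:
    """Assign every residue in the profile to a bin of ``scheme``.

    Returns a table indexed by residue with columns ``bin`` (label) and
    ``rank`` (0 = lightest). Missing residues get the darkest bin.
    """
    labels = []
    for _, row in profile.table.iterrows():
        if row["missing"]:
            labels.append(scheme.darkest)
        else:
            labels.append(scheme.assign(row["percent_change"]))
    return pd.DataFrame(
        {"bin": labels, "rank": [scheme.rank(l) for l in labels]},
        index=profile.table.index,
    )


@dataclass(frozen=True)
class BindingRegion:
    """A contiguous stretch of attenuated residues (inclusive endpoints)."""

    start_residue: int
    end_residue: int
    mean_percent_change: float

    @property
    def length(self) -> int:
        return self.end_residue - self.start_residue + 1

    def as_tuple(self) -> tuple[int, int]:
        return (self.start_residue, self.end_residue)


def detect_binding_regions(
    profile: ResidueIntensityProfile,
    change_threshold: float = 0.5,
    min_run: int = 4,
    max_gap: int = 1,
) -> list[BindingRegion]:
    """Maximal contiguous runs of attenuated residues.

    A residue is a *hit* when its percent_change (fraction) is >=
    ``change_threshold``. Hits separated by at most ``max_gap`` scored
    below-threshold residues belong to the same region. Missing residues
    carry no information and never break a run (the surface-colouring
    convention treats them like strongly attenuated residues); after runs
    are delimited by their outermost hits, boundaries are extended across up
    to ``max_gap`` directly adjacent missing residues, since overlap gaps at
    a motif edge are plausibly part of the footprint. Regions shorter than
    ``min_run`` residues (span, inclusive) are discarded.
    """
    tab = profile.table
    residues = tab.index.to_numpy()
    if residues.size == 0:
        return []
    change = tab["percent_change"].to_numpy(float)
    missing = tab["missing"].to_numpy(bool)
    hit = ~missing & (change >= change_threshold)

    # group hits: consecutive hits stay together while the scored (non-missing)
    # below-threshold residues between them number <= max_gap
    hit_idx = np.flatnonzero(hit)
    runs: list[tuple[int, int]] = []
    for i in hit_idx:
        if runs:
            prev = runs[-1][1]
            between = slice(prev + 1, i)
            n_below = int(np.sum(~missing[between] & ~hit[between]))
            if n_below <= max_gap:
                runs[-1] = (runs[-1][0], i)
                continue
        runs.append((i, i))

    regions = []
    n = len(residues)
    for lo, hi in runs:
        # extend across adjacent missing residues, at most max_gap each side
        ext_lo = lo
        while ext_lo - 1 >= 0 and missing[ext_lo - 1] and lo - ext_lo < max_gap:
            ext_lo -= 1
        ext_hi = hi
        while ext_hi + 1 < n and missing[ext_hi + 1] and ext_hi - hi < max_gap:
            ext_hi += 1
        start, end = int(residues[ext_lo]), int(residues[ext_hi])
        if end - start + 1 < min_run:
            continue
        span = change[ext_lo : ext_hi + 1]
        regions.append(
            BindingRegion(
                start_residue=start,
                end_residue=end,
                mean_percent_change=float(np.nanmean(span)),
            )
        )
    return sorted(regions, key=lambda r: r.start_residue)


def export_attributes(bins: pd.DataFrame, chain_id: str, out_path) -> None:
    """Write a tab-separated residue -> bin-rank attribute file.

    Header comment lines record the chain and the rank -> label legend
    (rank 0 = lightest = strongest attenuation); data lines are
    ``residue<TAB>rank``. Output is byte-deterministic for identical input.
    """
    out_path = Path(out_path)
    lines = [f"# chain\t{chain_id}"]
    legend = (
        bins[["rank", "bin"]].drop_duplicates().sort_values("rank")
        if len(bins)
        else pd.DataFrame(columns=["rank", "bin"])
    )
    for _, row in legend.iterrows():
        lines.append(f"# rank\t{int(row['rank'])}\t{row['bin']}")
    lines.append("residue\trank")
    for res, row in bins.sort_index().iterrows():
        lines.append(f"{int(res)}\t{int(row['rank'])}")
    out_path.write_text("\n".join(lines) + "\n")
    if not len(bins):
        warnings.warn(f"{out_path}: no binned residues; wrote header only", RuntimeWarning,
                      stacklevel=2)


def read_attributes(path) -> pd.DataFrame:
    """Re-read an attribute file written by :func:`export_attributes`."""
    path = Path(path)
    ranks: dict[int, str] = {}
    rows = []
    for line in path.read_text().splitlines():
        if line.startswith("# rank"):
            parts = line.split("\t")
            ranks[int(parts[1])] = parts[2]
        elif line.startswith("#") or line == "residue\trank":
            continue
        elif line.strip():
            res, rank = line.split("\t")
            rows.append((int(res), int(rank)))
    df = pd.DataFrame(rows, columns=["residue", "rank"]).set_index("residue")
    df["bin"] = [ranks.get(r, "") for r in df["rank"]]
    return df[["bin", "rank"]]


def write_profile_csv(
    profile: ResidueIntensityProfile, bins: pd.DataFrame, out_path
) -> None:
    """Write the per-residue profile CSV
    (``residue,percent_change,bin,missing_reason``)."""
    out = pd.DataFrame(
        {
            "residue": profile.table.index,
            "percent_change": profile.table["percent_change"].to_numpy(),
            "bin": bins["bin"].to_numpy(),
            "missing_reason": profile.table["missing_reason"].to_numpy(),
        }
    )
    out.to_csv(out_path, index=False)
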