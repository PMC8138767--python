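"""Per-cell substrate expression vs receptor-localization statistics.

Input is a per-cell table (one row per analysed cell): mean nuclear GFP
intensity of the substrate and a binary localization class of the adaptor
protein, ``"speckled"`` (punctate, including mixed diffuse+punctate cells)
or ``"diffuse"``. The analysis summarises the intensity distribution per
class (violin-ready quantiles plus raw points) and tests whether the
diffuse-class cells express more substrate than the speckled-class cells
with a two-tailed two-sample Student's t test (pooled variance by default;
Welch available). Cells are the unit of analysis, pooled across biological
replicates; per-replicate counts are reported for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CellTableError",
    "GroupComparison",
    "CLASSES",
    "validate_cell_table",
    "summarize_by_class",
    "compare_classes",
    "read_cell_csv",
]

CLASSES = ("diffuse", "speckled")
_REQUIRED = ["cell_id", "replicate", "variant", "mean_gfp_intensity", "spop_class"]
_VIOLIN_QUANTILES = (0.05, 0.25, 0.50, 0.75, 0.95)


class CellTableError(ValueError):
    """Malformed per-cell table."""


def validate_cell_table(records: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, non-negative intensities, binary class labels."""
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise CellTableError(f"cell table missing column(s): {missing}")
    if len(records) == 0:
        raise CellTableError("cell table is empty")
    bad = set(records["spop_class"].unique()) - set(CLASSES)
    if bad:
        raise CellTableError(
            f"spop_class must be one of {CLASSES}; found {sorted(bad)} "
            "(cells with mixed diffuse+punctate signal are binned as 'speckled')"
        )
    if (records["mean_gfp_intensity"] < 0).any():
        raise CellTableError("mean_gfp_intensity must be non-negative")
    return records


def _select_variant(records: pd.DataFrame, variant: str | None) -> pd.DataFrame:
    if variant is None:
        return records
    sub = records[records["variant"] == variant]
    if len(sub) == 0:
        known = sorted(records["variant"].unique())
        raise CellTableError(f"no cells for variant {variant!r}; variants present: {known}")
    return sub


def summarize_by_class(records: pd.DataFrame, variant: str | None = None) -> dict:
    """Violin-ready per-class summary of nuclear GFP intensity.

    Returns, per present class: n, mean, sd, min, max, the quantiles used
    for violin rendering, per-replicate cell counts, and the raw points.
    A flag lists any absent class.
    """
    records = validate_cell_table(records)
    sub = _select_variant(records, variant)
    summary: dict = {"variant": variant, "classes": {}, "absent_classes": []}
    for cls in CLASSES:
        grp = sub[sub["spop_class"] == cls]["mean_gfp_intensity"].to_numpy(float)
        if grp.size == 0:
            summary["absent_classes"].append(cls)
            continue
        reps = sub[sub["spop_class"] == cls]["replicate"]
        summary["classes"][cls] = {
            "n": int(grp.size),
            "mean": float(np.mean(grp)),
            "sd": float(np.std(grp, ddof=1)) if grp.size > 1 else float("nan"),
            "min": float(np.min(grp)),
            "max": float(np.max(grp)),
            "quantiles": {str(q): float(np.quantile(grp, q)) for q in _VIOLIN_QUANTILES},
            "per_replicate_n": {str(k): int(v) for k, v in reps.value_counts().items()},
            "points": [float(x) for x in grp],
        }
    return summary


@dataclass
class GroupComparison:
    """Two-tailed two-sample t test of diffuse vs speckled intensity.

    The t statistic carries the sign of (diffuse mean - speckled mean).
    ``applicable`` is False (with a reason) when one class has fewer than
    two cells or the pooled variance is zero; the test is only meaningful
    for variants showing two distinct localization patterns.
    """

    applicable: bool
    reason: str = ""
    variant: str | None = None
    n_diffuse: int = 0
    n_speckled: int = 0
    t_statistic: float = float("nan")
    p_value: float = float("nan")
    degrees_of_freedom: float = float("nan")
    method: str = "student"
    class_stats: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "applicable": self.applicable,
            "reason": self.reason,
            "variant": self.variant,
            "n_diffuse": self.n_diffuse,
            "n_speckled": self.n_speckled,
            "t_statistic": None if np.isnan(self.t_statistic) else self.t_statistic,
            "p_value": None if np.isnan(self.p_value) else self.p_value,
            "degrees_of_freedom": (
                None if np.isnan(self.degrees_of_freedom) else self.degrees_of_freedom
            ),
            "method": self.method,
            "class_stats": self.class_stats,
        }


def compare_classes(
    records: pd.DataFrame, variant: str | None = None, method: str = "student"
) -> GroupComparison:
    """Test whether diffuse-class cells express more substrate than
    speckled-class cells (two-tailed, alpha at the caller's discretion).

    ``method`` is ``"student"`` (pooled variance, df = n1+n2-2) or
    ``"welch"``. Degenerate inputs yield a not-applicable result rather
    than an exception.
    """
    if method not in ("student", "welch"):
        raise CellTableError(f"unknown test method {method!r}")
    records = validate_cell_table(records)
    sub = _select_variant(records, variant)
    diffuse = sub[sub["spop_class"] == "diffuse"]["mean_gfp_intensity"].to_numpy(float)
    speckled = sub[sub["spop_class"] == "speckled"]["mean_gfp_intensity"].to_numpy(float)
    base = GroupComparison(
        applicable=False,
        variant=variant,
        n_diffuse=int(diffuse.size),
        n_speckled=int(speckled.size),
        method=method,
        class_stats={
            cls: {"n": int(g.size), "mean": float(np.mean(g)) if g.size else None}
            for cls, g in (("diffuse", diffuse), ("speckled", speckled))
        },
    )
    if diffuse.size < 2 or speckled.size < 2:
        base.reason = "each class needs >= 2 cells (single localization pattern?)"
        return base
    if np.var(diffuse, ddof=1) == 0 and np.var(speckled, ddof=1) == 0:
        base.reason = "zero pooled variance"
        return base
    res = stats.ttest_ind(diffuse, speckled, equal_var=(method == "student"))
    base.applicable = True
    base.t_statistic = float(res.statistic)
    base.p_value = float(res.pvalue)
    base.degrees_of_freedom = float(res.df)
    return base


def read_cell_csv(path) -> pd.DataFrame:
    """Read and validate a per-cell CSV
    (``cell_id,replicate,variant,mean_gfp_intensity,spop_class``)."""
    df = pd.read_csv(path)
    return validate_cell_table(df)
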