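"""Dissociation-constant estimation from anisotropy titrations.

Two experiment geometries are supported:

* **direct** titration: receptor is titrated into a fixed concentration of
  labelled probe; the depletion-corrected single-site isotherm is fit for
  K_D together with the free/bound anisotropy endpoints.
* **competition** titration: an unlabelled competitor is serially diluted
  into a fixed probe + receptor mixture; the exact ternary competitive
  equilibrium is fit for the competitor K_D (K_B), with the probe K_D (K_A)
  and the totals fixed from the direct experiment.

Each replicate is fit independently and the per-replicate dissociation
constants are aggregated as mean +/- SEM, matching the convention of
reporting an average K_D with standard error across experiments. K values
are optimised in log10 space (they span many orders of magnitude across
constructs) with a grid-search initialisation; for fixed g = 1 the
endpoint anisotropies enter the model linearly and are profiled out in
closed form during the grid stage.

Titrations that never approach saturation of the competitive displacement
(e.g. solubility-limited competitors) cannot pin down K_B from above; such
fits are classified ``lower_bound_only`` and should be read as "K_D >
reported value".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .equilibrium import (
    AnisotropyEndpoints,
    _free_receptor_grid,
    direct_fraction_bound,
    predict_anisotropy,
)

__all__ = [
    "TitrationSeries",
    "AffinityFitResult",
    "FitError",
    "TitrationError",
    "fit_direct",
    "fit_competition",
    "aggregate_replicates",
    "classify_bound_estimate",
    "read_titration_csv",
    "write_titration_csv",
]

# log10(K/M) grid used to initialise the nonlinear fit
_GRID_LO, _GRID_HI, _GRID_N = -9.0, -1.0, 41

STATUS_POINT = "point_estimate"
STATUS_LOWER_BOUND = "lower_bound_only"


class TitrationError(ValueError):
    """Malformed or degenerate titration input."""


class FitError(RuntimeError):
    """Raised when a titration cannot be fit (non-identifiable, degenerate)."""


@dataclass
class TitrationSeries:
    """One anisotropy titration with replicate structure.

    ``data`` columns: ``titrant_conc`` (M; receptor total in direct mode,
    competitor total in competition mode), ``anisotropy``, ``replicate``.
    """

    mode: str  # "direct" | "competition"
    data: pd.DataFrame
    probe_total: float  # A_T (M), both modes
    receptor_total: float | None = None  # R_T (M), competition mode
    probe_kd: float | None = None  # K_A (M), competition mode

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "competition"):
            raise TitrationError(f"unknown titration mode {self.mode!r}")
        missing = {"titrant_conc", "anisotropy", "replicate"} - set(self.data.columns)
        if missing:
            raise TitrationError(f"titration table missing columns: {sorted(missing)}")
        if self.probe_total <= 0:
            raise TitrationError("probe_total must be positive")
        if self.mode == "competition":
            if self.receptor_total is None or self.probe_kd is None:
                raise TitrationError("competition mode requires receptor_total and probe_kd")
            if self.receptor_total <= 0 or self.probe_kd <= 0:
                raise TitrationError("receptor_total and probe_kd must be positive")

    def replicate_ids(self) -> list:
        return list(pd.unique(self.data["replicate"]))

    def replicate(self, rep_id) -> tuple[np.ndarray, np.ndarray]:
        """Concentration axis and anisotropy of one replicate, sorted ascending."""
        sub = self.data[self.data["replicate"] == rep_id].sort_values("titrant_conc")
        return sub["titrant_conc"].to_numpy(float), sub["anisotropy"].to_numpy(float)

    def validate_for_fit(self, min_points: int = 4) -> None:
        conc = self.data["titrant_conc"].to_numpy(float)
        if np.any(conc < 0):
            raise TitrationError("titrant concentrations must be non-negative")
        for rep in self.replicate_ids():
            x, _ = self.replicate(rep)
            informative = np.unique(x[x > 0])
            if informative.size < min_points:
                raise FitError(
                    f"replicate {rep!r}: only {informative.size} informative "
                    f"(positive, distinct) titrant concentrations; need >= {min_points}"
                )


@dataclass
class AffinityFitResult:
    """Aggregated K_D estimate from per-replicate fits."""

    kd_mean: float
    kd_sem: float  # NaN when undefined (single replicate)
    per_replicate_kds: list[float]
    endpoints: AnisotropyEndpoints
    status: str  # point_estimate | lower_bound_only
    residual_rms: float
    converged: bool
    mode: str
    sem_defined: bool = True
    probe_total: float | None = None
    receptor_total: float | None = None
    probe_kd: float | None = None
    max_titrant: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        """JSON-serialisable report."""
        return {
            "mode": self.mode,
            "kd_mean_M": self.kd_mean,
            "kd_sem_M": self.kd_sem if self.sem_defined else None,
            "per_replicate_kds_M": list(self.per_replicate_kds),
            "n_replicates": len(self.per_replicate_kds),
            "status": self.status,
            "endpoints": {
                "r_free": self.endpoints.r_free,
                "r_bound": self.endpoints.r_bound,
                "g": self.endpoints.g,
            },
            "residual_rms": self.residual_rms,
            "converged": self.converged,
            "warnings": list(self.warnings),
        }

    def summary(self) -> str:
        """Human-readable report; lower bounds render as 'K_D > value'."""
        if self.status == STATUS_LOWER_BOUND:
            kd_line = f"K_D > {self.kd_mean * 1e6:.3g} uM (lower bound: titration unsaturated)"
        else:
            sem = f" +/- {self.kd_sem * 1e6:.3g}" if self.sem_defined else ""
            kd_line = f"K_D = {self.kd_mean * 1e6:.3g}{sem} uM"
        lines = [
            f"{self.mode} anisotropy fit ({len(self.per_replicate_kds)} replicate(s))",
            kd_line,
            f"endpoints: r_free={self.endpoints.r_free:.4f} "
            f"r_bound={self.endpoints.r_bound:.4f} g={self.endpoints.g:.3g}",
            f"residual rms: {self.residual_rms:.2e} anisotropy units",
            f"converged: {self.converged}",
        ]
        lines += [f"warning: {w}" for w in self.warnings]
        return "\n".join(lines)


def aggregate_replicates(per_replicate_kds) -> tuple[float, float]:
    """Mean and standard error of the mean of per-replicate K_D estimates.

    SEM is the sample standard deviation (ddof=1) over sqrt(n). For a single
    replicate the SEM is undefined: NaN is returned with a warning.
    """
    kds = np.asarray(list(per_replicate_kds), dtype=float)
    if kds.size == 0:
        raise FitError("cannot aggregate an empty list of replicate estimates")
    mean = float(np.mean(kds))
    if kds.size == 1:
        warnings.warn("single replicate: SEM undefined", RuntimeWarning, stacklevel=2)
        return mean, float("nan")
    sem = float(np.std(kds, ddof=1) / np.sqrt(kds.size))
    return mean, sem


def _model_direct(conc, log10_kd, r_free, r_bound, g, probe_total):
    fb = direct_fraction_bound(probe_total, conc, 10.0**log10_kd)
    return predict_anisotropy(fb, AnisotropyEndpoints(r_free, r_bound, g))


def _model_competition(conc, log10_kb, r_free, r_bound, g, probe_total, receptor_total, probe_kd):
    r = _free_receptor_grid(receptor_total, probe_total, conc, probe_kd, 10.0**log10_kb)
    fsb = r / (probe_kd + r)
    return predict_anisotropy(fsb, AnisotropyEndpoints(r_free, r_bound, g))


def _profile_endpoints(fb: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form least-squares endpoints for g=1, where the model is
    linear in (r_free, r_bound): r = r_free (1-FB) + r_bound FB.
    Returns (r_free, r_bound, sse)."""
    design = np.column_stack([1.0 - fb, fb])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def _grid_init(fb_grid: np.ndarray, y: np.ndarray, log10_ks: np.ndarray):
    """Pick the grid K (row of fb_grid) whose profiled-endpoint fit has the
    smallest SSE. Returns (log10_k, r_free, r_bound)."""
    best = None
    for lk, fb in zip(log10_ks, fb_grid):
        rf, rb, sse = _profile_endpoints(fb, y)
        if best is None or sse < best[0]:
            best = (sse, lk, rf, rb)
    return best[1], best[2], best[3]


def _fit_one_replicate(x, y, model, model_kwargs, g, k_name: str):
    """Fit one replicate; returns (kd, endpoints, residuals, converged, notes)."""
    notes: list[str] = []
    if np.ptp(y) < 1e-12:
        raise FitError("flat anisotropy series: binding signal absent, K not identifiable")

    log10_ks = np.linspace(_GRID_LO, _GRID_HI, _GRID_N)
    if model is _model_direct:
        fb_grid = np.stack(
            [direct_fraction_bound(model_kwargs["probe_total"], x, 10.0**lk) for lk in log10_ks]
        )
    else:
        r = _free_receptor_grid(
            model_kwargs["receptor_total"],
            model_kwargs["probe_total"],
            x[None, :],
            model_kwargs["probe_kd"],
            10.0 ** log10_ks[:, None],
        )
        fb_grid = r / (model_kwargs["probe_kd"] + r)
    lk0, rf0, rb0 = _grid_init(fb_grid, y, log10_ks)

    params = lmfit.Parameters()
    params.add("log10_k", value=lk0, min=_GRID_LO, max=_GRID_HI)
    params.add("r_free", value=rf0)
    params.add("r_bound", value=rb0)
    g_free = g == "free"
    params.add("g", value=1.0 if g_free else float(g), vary=g_free, min=1e-3, max=1e3)

    def residual(p):
        return (
            model(x, p["log10_k"].value, p["r_free"].value, p["r_bound"].value, p["g"].value,
                  **model_kwargs)
            - y
        )

    out = lmfit.minimize(residual, params, method="leastsq")
    p = out.params
    kd = 10.0 ** p["log10_k"].value
    endpoints = AnisotropyEndpoints(p["r_free"].value, p["r_bound"].value, p["g"].value)
    converged = bool(out.success)
    # K pinned at the optimizer bounds cannot be trusted as an estimate
    if abs(p["log10_k"].value - _GRID_LO) < 1e-6 or abs(p["log10_k"].value - _GRID_HI) < 1e-6:
        converged = False
        notes.append(f"{k_name} pinned at optimiser bound (log10 K = {p['log10_k'].value:.2f})")
    if abs(endpoints.r_bound - endpoints.r_free) < 1e-9:
        raise FitError("fitted dynamic range collapsed: K not identifiable")
    return kd, endpoints, np.asarray(out.residual), converged, notes


def _fit_series(series: TitrationSeries, model, model_kwargs, g, k_name: str):
    series.validate_for_fit()
    per_kds, per_eps, resids, notes = [], [], [], []
    n_failed = 0
    for rep in series.replicate_ids():
        x, y = series.replicate(rep)
        keep = x > 0  # zero-concentration wells are endpoint controls, not titrant points
        try:
            kd, eps, res, conv, rep_notes = _fit_one_replicate(
                x[keep], y[keep], model, model_kwargs, g, k_name
            )
        except FitError:
            raise
        if conv:
            per_kds.append(kd)
            per_eps.append(eps)
            resids.append(res)
            notes.extend(rep_notes)
        else:
            n_failed += 1
            notes.append(f"replicate {rep!r} excluded from aggregation (not converged)")
            warnings.warn(
                f"replicate {rep!r} fit did not converge; excluded", RuntimeWarning, stacklevel=3
            )
    if not per_kds:
        raise FitError(f"no replicate converged ({n_failed} failed)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        kd_mean, kd_sem = aggregate_replicates(per_kds)
    sem_defined = len(per_kds) > 1
    if not sem_defined:
        notes.append("single replicate: SEM undefined")
    endpoints = AnisotropyEndpoints(
        float(np.mean([e.r_free for e in per_eps])),
        float(np.mean([e.r_bound for e in per_eps])),
        float(np.mean([e.g for e in per_eps])),
    )
    all_res = np.concatenate(resids)
    return AffinityFitResult(
        kd_mean=kd_mean,
        kd_sem=kd_sem,
        per_replicate_kds=per_kds,
        endpoints=endpoints,
        status=STATUS_POINT,
        residual_rms=float(np.sqrt(np.mean(all_res**2))),
        converged=n_failed == 0,
        mode=series.mode,
        sem_defined=sem_defined,
        probe_total=series.probe_total,
        receptor_total=series.receptor_total,
        probe_kd=series.probe_kd,
        max_titrant=float(series.data["titrant_conc"].max()),
        warnings=notes,
    )


def fit_direct(series: TitrationSeries, g=1.0) -> AffinityFitResult:
    """Fit a direct receptor-into-probe titration for K_D and endpoints.

    ``g`` is the bound/free intensity ratio: a number fixes it (default 1,
    pure anisotropy mixing), the string ``"free"`` floats it.
    """
    if series.mode != "direct":
        raise TitrationError("fit_direct requires a direct-mode series")
    return _fit_series(
        series, _model_direct, {"probe_total": series.probe_total}, g, k_name="K_D"
    )


def fit_competition(
    series: TitrationSeries, g=1.0, saturation_threshold: float = 0.8
) -> AffinityFitResult:
    """Fit a competition titration for the competitor K_D (K_B).

    A_T, R_T and K_A are fixed from the series metadata (measured in the
    direct experiment). After fitting, the result is classified as a point
    estimate or a lower bound via :func:`classify_bound_estimate`.
    """
    if series.mode != "competition":
        raise TitrationError("fit_competition requires a competition-mode series")
    kwargs = {
        "probe_total": series.probe_total,
        "receptor_total": series.receptor_total,
        "probe_kd": series.probe_kd,
    }
    result = _fit_series(series, _model_competition, kwargs, g, k_name="K_B")
    result.status = classify_bound_estimate(
        result, max_titrant=result.max_titrant, saturation_threshold=saturation_threshold
    )
    return result


def classify_bound_estimate(
    fit: AffinityFitResult, max_titrant: float, saturation_threshold: float = 0.8
) -> str:
    """Classify a competition fit as a point estimate or a lower bound.

    Computes the model-predicted displacement of the probe at the highest
    competitor concentration reached, as a fraction of the zero-competitor
    probe occupancy (the fitted dynamic range). If that displacement falls
    below ``saturation_threshold`` the titration never approached the
    saturated baseline and only "K_D > kd_mean" is defensible.
    """
    if fit.mode != "competition":
        return STATUS_POINT
    if saturation_threshold <= 0:
        return STATUS_POINT
    if not fit.converged and not fit.per_replicate_kds:
        return STATUS_LOWER_BOUND
    r0 = _free_receptor_grid(
        fit.receptor_total, fit.probe_total, 0.0, fit.probe_kd, fit.kd_mean
    )
    rmax = _free_receptor_grid(
        fit.receptor_total, fit.probe_total, max_titrant, fit.probe_kd, fit.kd_mean
    )
    fsb0 = float(r0) / (fit.probe_kd + float(r0))
    fsb_max = float(rmax) / (fit.probe_kd + float(rmax))
    if fsb0 <= 0:
        return STATUS_LOWER_BOUND
    displacement = (fsb0 - fsb_max) / fsb0
    return STATUS_LOWER_BOUND if displacement < saturation_threshold else STATUS_POINT


# ---------------------------------------------------------------------------
# CSV dialect: titrant_conc, conc_unit, anisotropy, replicate

def read_titration_csv(
    path,
    mode: str,
    probe_total: float,
    receptor_total: float | None = None,
    probe_kd: float | None = None,
) -> TitrationSeries:
    """Read a titration table (columns titrant_conc, conc_unit, anisotropy,
    replicate) into a :class:`TitrationSeries`, converting to molar."""
    from .units import to_molar

    df = pd.read_csv(path)
    required = ["titrant_conc", "conc_unit", "anisotropy", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TitrationError(f"{path}: missing required column(s): {missing}")
    if len(df) == 0:
        raise TitrationError(f"{path}: no data rows")
    conc = [to_molar(v, u) for v, u in zip(df["titrant_conc"], df["conc_unit"])]
    data = pd.DataFrame(
        {
            "titrant_conc": conc,
            "anisotropy": df["anisotropy"].astype(float),
            "replicate": df["replicate"],
        }
    )
    return TitrationSeries(
        mode=mode,
        data=data,
        probe_total=probe_total,
        receptor_total=receptor_total,
        probe_kd=probe_kd,
    )


def write_titration_csv(series: TitrationSeries, path, unit: str = "uM") -> None:
    """Write a series in the titration CSV dialect with explicit units."""
    from .units import from_molar

    out = pd.DataFrame(
        {
            "titrant_conc": [from_molar(v, unit) for v in series.data["titrant_conc"]],
            "conc_unit": unit,
            "anisotropy": series.data["anisotropy"],
            "replicate": series.data["replicate"],
        }
    )
    out.to_csv(path, index=False)
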