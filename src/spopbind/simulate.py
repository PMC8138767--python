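"""Synthetic data generators for every pipeline stage.

The generators emit data with the statistical structure each analysis stage
assumes, so the whole pipeline can be exercised and validated closed-loop
without experimental downloads. Defaults reproduce the study conditions the
analyses were designed for:

* competition titrations at 40 nM labelled probe and 6 uM receptor, with
  the competitor in 12 three-fold serial dilutions from 2 mM (down to
  ~0.011 uM), >= 3 replicates, additive Gaussian anisotropy noise
  (sd 0.005, a plausible plate-reader figure),
* direct titrations with receptor log-spaced over 0.001-300 uM,
* peak lists over a disordered-region window (residues 204-283) with
  attenuation planted in two motif regions (220-235 and 265-275) and a
  configurable fraction of overlap-missing residues; intensity noise is
  multiplicative log-normal (positivity-preserving),
* per-cell tables in which the probability of diffuse adaptor localization
  is a logistic function of log nuclear substrate intensity (a
  concentration-threshold model); slope 0 gives the null model, and
  binding-incompetent variants force the speckled class regardless of
  expression.

Every generator takes an explicit seed (via :class:`SimulationConfig`) and
is fully deterministic given it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .equilibrium import (
    AnisotropyEndpoints,
    _free_receptor_grid,
    direct_fraction_bound,
    predict_anisotropy,
)
from .fitting import TitrationSeries

__all__ = [
    "SimulationConfig",
    "TitrationDesign",
    "NMRDesign",
    "CellDesign",
    "SimulationError",
    "gen_direct_titration",
    "gen_competition_titration",
    "gen_nmr_titration",
    "gen_cell_table",
]


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class TitrationDesign:
    """Concentration design of the anisotropy experiments (all in M)."""

    probe_total: float = 40e-9  # 40 nM labelled probe
    receptor_total: float = 6e-6  # 6 uM receptor in competition mode
    direct_min: float = 1e-9  # direct mode receptor range 0.001-300 uM
    direct_max: float = 300e-6
    direct_n_points: int = 12
    competitor_top: float = 2e-3  # competitor serial dilution from 2 mM
    dilution_factor: float = 3.0
    competition_n_points: int = 12


@dataclass(frozen=True)
class NMRDesign:
    """Design of the synthetic titration peak lists."""

    window: tuple[int, int] = (204, 283)
    # (start, end, attenuation depth) per planted motif region
    regions: tuple[tuple[int, int, float], ...] = ((220, 235, 0.85), (265, 275, 0.80))
    missing_fraction: float = 0.10
    noise_sd_intensity: float = 0.10  # log-normal sigma, per dataset
    apo_sigma: float = 0.3  # log-normal spread of apo intensities
    base_intensity: float = 1e6  # arbitrary units
    bound_scale: float = 1.5  # global gain difference between datasets


@dataclass(frozen=True)
class CellDesign:
    """Design of the per-cell localization tables."""

    n_cells: int = 90
    n_replicates: int = 3
    intensity_median: float = 500.0  # grayscale units
    intensity_sigma: float = 0.8  # log-normal sigma
    localization_midpoint: float = 500.0  # intensity at P(diffuse) = 0.5
    localization_slope: float = 3.0  # logistic slope in log-intensity; 0 = null


@dataclass(frozen=True)
class SimulationConfig:
    """Seed plus per-stage designs; the seed is required and explicit."""

    seed: int
    noise_sd_anisotropy: float = 0.005
    n_replicates: int = 3
    titration: TitrationDesign = field(default_factory=TitrationDesign)
    nmr: NMRDesign = field(default_factory=NMRDesign)
    cells: CellDesign = field(default_factory=CellDesign)

    def __post_init__(self) -> None:
        if self.noise_sd_anisotropy < 0:
            raise SimulationError("noise_sd_anisotropy must be >= 0")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def gen_direct_titration(
    kd: float, config: SimulationConfig, endpoints: AnisotropyEndpoints | None = None
) -> TitrationSeries:
    """Direct receptor-into-probe titration at a known K_D."""
    if kd <= 0:
        raise SimulationError("kd must be positive")
    endpoints = endpoints or AnisotropyEndpoints()
    d = config.titration
    if d.direct_n_points < 2 or d.direct_min <= 0 or d.direct_max <= d.direct_min:
        raise SimulationError("invalid direct titration design")
    rng = config.rng()
    conc = np.geomspace(d.direct_min, d.direct_max, d.direct_n_points)
    fb = direct_fraction_bound(d.probe_total, conc, kd)
    r_model = predict_anisotropy(fb, endpoints)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        noise = rng.normal(0.0, config.noise_sd_anisotropy, size=conc.size)
        rows.append(
            pd.DataFrame(
                {"titrant_conc": conc, "anisotropy": r_model + noise, "replicate": f"rep{rep}"}
            )
        )
    return TitrationSeries(
        mode="direct", data=pd.concat(rows, ignore_index=True), probe_total=d.probe_total
    )


def gen_competition_titration(
    k_b: float,
    config: SimulationConfig,
    k_a: float = 2.6e-6,
    endpoints: AnisotropyEndpoints | None = None,
) -> TitrationSeries:
    """Competitor serial-dilution titration at known K_A and K_B."""
    if k_a <= 0 or k_b <= 0:
        raise SimulationError("k_a and k_b must be positive")
    endpoints = endpoints or AnisotropyEndpoints()
    d = config.titration
    if d.competition_n_points < 2 or d.competitor_top <= 0 or d.dilution_factor <= 1:
        raise SimulationError("invalid competition titration design")
    rng = config.rng()
    conc = d.competitor_top / d.dilution_factor ** np.arange(d.competition_n_points)
    conc = np.sort(conc)
    r_free = _free_receptor_grid(d.receptor_total, d.probe_total, conc, k_a, k_b)
    fsb = r_free / (k_a + r_free)
    r_model = predict_anisotropy(fsb, endpoints)
    rows = []
    for rep in range(1, config.n_replicates + 1):
        noise = rng.normal(0.0, config.noise_sd_anisotropy, size=conc.size)
        rows.append(
            pd.DataFrame(
                {"titrant_conc": conc, "anisotropy": r_model + noise, "replicate": f"rep{rep}"}
            )
        )
    return TitrationSeries(
        mode="competition",
        data=pd.concat(rows, ignore_index=True),
        probe_total=d.probe_total,
        receptor_total=d.receptor_total,
        probe_kd=k_a,
    )


def gen_nmr_titration(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired apo/bound peak lists with planted attenuation regions.

    Returns ``(apo, bound, truth)`` where the tables have columns
    ``residue, intensity`` and ``truth`` records the planted regions,
    depths, and the residues removed as overlap-missing (absent from the
    bound list). Missing residues are planted uniformly over the window.
    """
    d = config.nmr
    lo, hi = d.window
    spans = sorted((r[0], r[1]) for r in d.regions)
    for (s, e) in spans:
        if s < lo or e > hi or s > e:
            raise SimulationError(f"planted region ({s},{e}) outside window {d.window}")
    for (_, e1), (s2, _) in zip(spans, spans[1:]):
        if s2 <= e1:
            raise SimulationError("planted regions overlap")
    if not 0 <= d.missing_fraction < 1:
        raise SimulationError("missing_fraction must be in [0, 1)")
    rng = config.rng()
    residues = np.arange(lo, hi + 1)
    n = residues.size
    apo_int = d.base_intensity * rng.lognormal(0.0, d.apo_sigma, size=n)
    depth = np.zeros(n)
    for s, e, dep in d.regions:
        depth[(residues >= s) & (residues <= e)] = dep
    bound_int = d.bound_scale * apo_int * (1.0 - depth)
    if d.noise_sd_intensity > 0:
        apo_int = apo_int * rng.lognormal(0.0, d.noise_sd_intensity, size=n)
        bound_int = bound_int * rng.lognormal(0.0, d.noise_sd_intensity, size=n)
    n_missing = int(round(d.missing_fraction * n))
    missing = np.sort(rng.choice(residues, size=n_missing, replace=False))
    apo = pd.DataFrame({"residue": residues, "intensity": apo_int})
    bound = pd.DataFrame({"residue": residues, "intensity": bound_int})
    bound = bound[~bound["residue"].isin(missing)].reset_index(drop=True)
    truth = {
        "regions": [(int(s), int(e)) for s, e, _ in d.regions],
        "depths": [float(dep) for _, _, dep in d.regions],
        "missing_residues": [int(r) for r in missing],
    }
    return apo, bound, truth


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gen_cell_table(
    config: SimulationConfig, variant: str = "WT", binding_competent: bool = True
) -> pd.DataFrame:
    """Per-cell table under the concentration-threshold localization model.

    Intensities are log-normal; P(diffuse) is a logistic function of log
    intensity centred on ``localization_midpoint`` with the configured
    slope. ``binding_competent=False`` emulates deletion variants that
    cannot draw the adaptor out of speckles: every cell is speckled
    regardless of expression. Cells are assigned round-robin to biological
    replicates.
    """
    d = config.cells
    if d.n_cells < 1:
        raise SimulationError("n_cells must be >= 1")
    if d.intensity_median <= 0 or d.localization_midpoint <= 0 or d.intensity_sigma <= 0:
        raise SimulationError("intensity parameters must be positive")
    rng = config.rng()
    intensity = d.intensity_median * rng.lognormal(0.0, d.intensity_sigma, size=d.n_cells)
    if binding_competent:
        p_diffuse = _logistic(
            d.localization_slope * (np.log(intensity) - np.log(d.localization_midpoint))
        )
    else:
        p_diffuse = np.zeros(d.n_cells)
    diffuse = rng.random(d.n_cells) < p_diffuse
    return pd.DataFrame(
        {
            "cell_id": [f"cell{i + 1:04d}" for i in range(d.n_cells)],
            "replicate": [f"bio{1 + i % d.n_replicates}" for i in range(d.n_cells)],
            "variant": variant,
            "mean_gfp_intensity": intensity,
            "spop_class": np.where(diffuse, "diffuse", "speckled"),
        }
    )
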