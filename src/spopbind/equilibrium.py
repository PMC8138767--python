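"""Closed-form binding equilibria for probe/competitor/receptor mixtures.

This module implements the equilibrium layer underneath fluorescence
anisotropy (FA) titration analysis:

* the single-site binding isotherm with explicit ligand depletion (the
  quadratic solution; valid when the bound fraction of the labelled probe
  is not negligible relative to its total),
* the exact ternary competitive equilibrium of a receptor R with two
  mutually exclusive ligands A (labelled probe) and B (unlabelled
  competitor), solved via the trigonometric root of the cubic in free
  receptor rather than via the excess-ligand approximation,
* intensity-weighted anisotropy prediction from the bound probe fraction,
* a brute-force bisection solver used as an independent numerical oracle.

All concentrations are in molar. The cubic closed form is polished with a
few Newton steps on the mass-balance residual: the raw trigonometric root
loses relative precision when one dissociation constant dwarfs the free
receptor concentration (catastrophic cancellation between the ``-a/3`` and
cosine terms), and the polish restores near machine accuracy at negligible
cost.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "EquilibriumSystem",
    "AnisotropyEndpoints",
    "SpeciesConcentrations",
    "EquilibriumError",
    "direct_fraction_bound",
    "competitive_free_receptor",
    "competitive_fraction_probe_bound",
    "predict_anisotropy",
    "oracle_solve_equilibrium",
]

# discriminant below this (M^6) is treated as degenerate -> oracle fallback
_DEGENERATE_DISC = 1e-30


class EquilibriumError(ValueError):
    """Invalid thermodynamic inputs (negative totals, non-positive K_D, ...)."""


@dataclass(frozen=True)
class EquilibriumSystem:
    """Total concentrations and dissociation constants of a competition mixture.

    Parameters
    ----------
    receptor_total
        Total receptor (binding-site) concentration R_T in M.
    probe_total
        Total labelled-probe concentration A_T in M.
    probe_kd
        Probe dissociation constant K_A in M.
    competitor_total
        Total competitor concentration B_T in M; 0 encodes "no competitor".
    competitor_kd
        Competitor dissociation constant K_B in M. Ignored physically when
        ``competitor_total`` is 0 but must still be positive.
    """

    receptor_total: float
    probe_total: float
    probe_kd: float
    competitor_total: float = 0.0
    competitor_kd: float = 1.0

    def __post_init__(self) -> None:
        if self.receptor_total < 0 or self.probe_total < 0 or self.competitor_total < 0:
            raise EquilibriumError("total concentrations must be non-negative")
        if self.probe_kd <= 0 or self.competitor_kd <= 0:
            raise EquilibriumError("dissociation constants must be positive")


@dataclass(frozen=True)
class AnisotropyEndpoints:
    """Anisotropy of the free and bound probe, plus the bound/free
    fluorescence-intensity ratio g used for intensity-weighted mixing.

    g = 1 corresponds to pure anisotropy mixing (no intensity change upon
    binding); it is the default because plate-reader FA experiments with
    fluorescein-labelled peptides typically show little quantum-yield change.
    """

    r_free: float = 0.08
    r_bound: float = 0.20
    g: float = 1.0

    def __post_init__(self) -> None:
        if self.g <= 0:
            raise EquilibriumError("intensity ratio g must be positive")


@dataclass(frozen=True)
class SpeciesConcentrations:
    """Free and complexed species at equilibrium (all in M)."""

    free_receptor: float
    free_probe: float
    free_competitor: float
    complex_probe: float
    complex_competitor: float


def direct_fraction_bound(probe_total, receptor_total, kd):
    """Fraction of probe bound in a two-species titration, with depletion.

    Solves the single-site equilibrium exactly (quadratic in the bound
    complex), so it remains valid when receptor binding depletes the probe:

        FB = (A_T + R_T + K_D - sqrt((A_T + R_T + K_D)^2 - 4 A_T R_T)) / (2 A_T)

    Parameters are broadcast elementwise; ``receptor_total`` is typically the
    titration axis. Returns values in [0, 1].
    """
    a_t = np.asarray(probe_total, dtype=float)
    r_t = np.asarray(receptor_total, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(a_t <= 0):
        raise EquilibriumError("probe_total must be positive")
    if np.any(k <= 0):
        raise EquilibriumError("kd must be positive")
    if np.any(r_t < 0):
        raise EquilibriumError("receptor_total must be non-negative")
    s = a_t + r_t + k
    disc = np.maximum(s * s - 4.0 * a_t * r_t, 0.0)
    fb = (s - np.sqrt(disc)) / (2.0 * a_t)
    fb = np.clip(fb, 0.0, 1.0)
    if fb.ndim == 0:
        return float(fb)
    return fb


def _free_receptor_grid(r_t, a_t, b_t, k_a, k_b, newton_steps: int = 3):
    """Vectorised exact free-receptor concentration of the ternary system.

    Computes the trigonometric root of the cubic in free receptor [R]:

        [R]^3 + a [R]^2 + b [R] + c = 0
        a = K_A + K_B + A_T + B_T - R_T
        b = K_B (A_T - R_T) + K_A (B_T - R_T) + K_A K_B
        c = -K_A K_B R_T
        theta = arccos[(-2 a^3 + 9 a b - 27 c) / (2 sqrt((a^2 - 3b)^3))]
        [R] = -a/3 + (2/3) sqrt(a^2 - 3b) cos(theta/3)

    then refines by Newton iteration on the scalar mass-balance residual
        f([R]) = [R] (1 + A_T/(K_A+[R]) + B_T/(K_B+[R])) - R_T.
    Inputs broadcast; returns an array of the broadcast shape.
    """
    r_t, a_t, b_t, k_a, k_b = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (r_t, a_t, b_t, k_a, k_b))
    )
    a = k_a + k_b + a_t + b_t - r_t
    b = k_b * (a_t - r_t) + k_a * (b_t - r_t) + k_a * k_b
    c = -k_a * k_b * r_t
    d2 = a * a - 3.0 * b

    out = np.empty(a.shape, dtype=float)
    degenerate = d2 <= _DEGENERATE_DISC
    ok = ~degenerate
    if np.any(ok):
        d2o = d2[ok]
        ao = a[ok]
        arg = (-2.0 * ao**3 + 9.0 * ao * b[ok] - 27.0 * c[ok]) / (2.0 * np.sqrt(d2o**3))
        theta = np.arccos(np.clip(arg, -1.0, 1.0))
        r = -ao / 3.0 + (2.0 / 3.0) * np.sqrt(d2o) * np.cos(theta / 3.0)
        r = np.clip(r, 0.0, r_t[ok])
        rt_o, at_o, bt_o = r_t[ok], a_t[ok], b_t[ok]
        ka_o, kb_o = k_a[ok], k_b[ok]
        for _ in range(newton_steps):
            f = r * (1.0 + at_o / (ka_o + r) + bt_o / (kb_o + r)) - rt_o
            df = 1.0 + at_o * ka_o / (ka_o + r) ** 2 + bt_o * kb_o / (kb_o + r) ** 2
            r = np.clip(r - f / df, 0.0, rt_o)
        out[ok] = r
    if np.any(degenerate):
        warnings.warn(
            "degenerate cubic discriminant; falling back to bisection oracle",
            RuntimeWarning,
            stacklevel=2,
        )
        idx = np.argwhere(degenerate)
        for i in idx:
            t = tuple(i)
            sys_i = EquilibriumSystem(
                receptor_total=float(r_t[t]),
                probe_total=float(a_t[t]),
                probe_kd=float(k_a[t]),
                competitor_total=float(b_t[t]),
                competitor_kd=float(k_b[t]),
            )
            out[t] = oracle_solve_equilibrium(sys_i).free_receptor
    return out


def competitive_free_receptor(system: EquilibriumSystem) -> float:
    """Exact free receptor concentration [R] (M) of a competition mixture."""
    r = _free_receptor_grid(
        system.receptor_total,
        system.probe_total,
        system.competitor_total,
        system.probe_kd,
        system.competitor_kd,
    )
    return float(r)


def competitive_fraction_probe_bound(system: EquilibriumSystem) -> float:
    """Fraction of the labelled probe bound, FSB = [R] / (K_A + [R])."""
    r = competitive_free_receptor(system)
    return r / (system.probe_kd + r)


def predict_anisotropy(frac_bound, endpoints: AnisotropyEndpoints):
    """Observed anisotropy for a given bound probe fraction.

    Intensity-weighted mixing of the free and bound endpoint anisotropies:

        r = (r_free (1 - FB) + g r_bound FB) / ((1 - FB) + g FB)

    With g = 1 this reduces to linear mixing. Accepts scalars or arrays.
    """
    fb = np.asarray(frac_bound, dtype=float)
    if np.any(fb < -1e-12) or np.any(fb > 1 + 1e-12):
        raise EquilibriumError("frac_bound must lie in [0, 1]")
    fb = np.clip(fb, 0.0, 1.0)
    g = endpoints.g
    r = (endpoints.r_free * (1.0 - fb) + g * endpoints.r_bound * fb) / ((1.0 - fb) + g * fb)
    if r.ndim == 0:
        return float(r)
    return r


def oracle_solve_equilibrium(
    system: EquilibriumSystem, tol: float = 1e-12, max_iter: int = 200
) -> SpeciesConcentrations:
    """Brute-force equilibrium solver by bisection on free receptor.

    The scalar residual f([R]) = [R] (1 + A_T/(K_A+[R]) + B_T/(K_B+[R])) - R_T
    is strictly increasing on [0, R_T] with f(0) <= 0 <= f(R_T), so bisection
    is guaranteed to bracket the unique root. Intended as an independent
    verifier of the closed-form solution and as a fallback for degenerate
    cubics; it is not used in the fitting hot path.

    ``tol`` is the relative interval-width target on [R]. Because the
    residual slope times the root never exceeds R_T, relative convergence of
    [R] to ``tol`` bounds the receptor mass-balance residual by ~tol * R_T.
    """
    if tol <= 0:
        raise EquilibriumError("tol must be positive")
    r_t = system.receptor_total
    a_t, b_t = system.probe_total, system.competitor_total
    k_a, k_b = system.probe_kd, system.competitor_kd
    if r_t == 0.0:
        return SpeciesConcentrations(0.0, a_t, b_t, 0.0, 0.0)

    def residual(r: float) -> float:
        return r * (1.0 + a_t / (k_a + r) + b_t / (k_b + r)) - r_t

    lo, hi = 0.0, r_t
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:  # interval at floating-point resolution
            break
        if residual(mid) > 0.0:
            hi = mid
        else:
            lo = mid
        if mid > 0.0 and (hi - lo) <= tol * mid:
            break
    else:
        raise EquilibriumError(
            f"bisection did not converge: interval {hi - lo:.3e} M, "
            f"residual {residual(0.5 * (lo + hi)):.3e} M after {max_iter} iterations"
        )
    r = 0.5 * (lo + hi)
    ra = a_t * r / (k_a + r)
    rb = b_t * r / (k_b + r)
    return SpeciesConcentrations(
        free_receptor=r,
        free_probe=a_t - ra,
        free_competitor=b_t - rb,
        complex_probe=ra,
        complex_competitor=rb,
    )
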