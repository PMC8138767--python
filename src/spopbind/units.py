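"""Concentration unit handling.

All model code works in molar (M). Tabular inputs carry an explicit unit
column (``conc_unit``); there is no unit guessing. Supported units span the
nM-mM range typical of peptide-binding experiments.
"""

from __future__ import annotations

# factors to molar; both micro signs accepted for convenience
_UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,  # µ (micro sign)
    "μM": 1e-6,  # μ (greek mu)
    "nM": 1e-9,
    "pM": 1e-12,
}


class UnitError(ValueError):
    """Raised for unknown concentration units."""


def to_molar(value: float, unit: str) -> float:
    """Convert a concentration from ``unit`` to molar."""
    try:
        factor = _UNIT_FACTORS[unit.strip()]
    except KeyError:
        known = ", ".join(sorted(set(_UNIT_FACTORS) - {"µM"}))
        raise UnitError(f"unknown concentration unit {unit!r}; expected one of: {known}") from None
    return float(value) * factor


def from_molar(value: float, unit: str) -> float:
    """Convert a concentration in molar to ``unit``."""
    try:
        factor = _UNIT_FACTORS[unit.strip()]
    except KeyError:
        raise UnitError(f"unknown concentration unit {unit!r}") from None
    return float(value) / factor
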