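"""Unit conventions and conversions.

Canonical in-memory units follow clinical convention: glucose in mmol/l,
peptide hormones in pmol/l, catecholamines and cortisol in nmol/l, growth
hormone in ug/l, glucose fluxes in mg/kg/min.

Conversion factors used throughout the package:

* glucose: 1 mmol/l = 18.016 mg/dl = 0.18016 mg/ml
  (molar mass of glucose 180.16 g/mol)
* insulin: 1 U = 6 nmol, hence 1 U/kg/h = 100 pmol/kg/min
"""

from __future__ import annotations

from .exceptions import UnitError

#: mg of glucose per ml per (mmol/l) — used wherever concentrations enter
#: mass-based flux arithmetic.
GLUCOSE_MMOL_L_TO_MG_ML = 0.18016

#: pmol of insulin per U.
INSULIN_U_TO_PMOL = 6000.0

# Directed conversion factors between recognised unit pairs.  Inverses are
# derived automatically, and chains are not attempted: every supported
# conversion is a single multiplication.
_FACTORS: dict[tuple[str, str], float] = {
    ("mmol/l", "mg/dl"): 18.016,
    ("mmol/l", "mg/ml"): GLUCOSE_MMOL_L_TO_MG_ML,
    ("mg/dl", "mg/ml"): 0.01,
    ("nmol/l", "pmol/l"): 1000.0,
    ("U", "nmol"): 6.0,
    ("U", "pmol"): INSULIN_U_TO_PMOL,
    ("U/kg/h", "pmol/kg/min"): INSULIN_U_TO_PMOL / 60.0,
    ("mU/l", "pmol/l"): 6.0,
    ("g", "mg"): 1000.0,
    ("h", "min"): 60.0,
}


def _factor(from_units: str, to_units: str) -> float:
    if from_units == to_units:
        return 1.0
    if (from_units, to_units) in _FACTORS:
        return _FACTORS[(from_units, to_units)]
    if (to_units, from_units) in _FACTORS:
        return 1.0 / _FACTORS[(to_units, from_units)]
    raise UnitError(f"no conversion registered for {from_units!r} -> {to_units!r}")


def convert_units(value, from_units: str, to_units: str):
    """Convert ``value`` between two recognised units.

    Identity conversions are exact; all others apply a single canonical
    factor, so round trips invert to machine precision.  Works on scalars
    and numpy arrays alike.

    Raises
    ------
    UnitError
        If the pair of units is not registered.
    """
    return value * _factor(from_units, to_units)


def can_convert(from_units: str, to_units: str) -> bool:
    """True if :func:`convert_units` accepts this pair."""
    try:
        _factor(from_units, to_units)
    except UnitError:
        return False
    return True
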