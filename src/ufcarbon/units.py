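"""Exact unit conversions used throughout the accounting pipeline.

All factors are rational and the arithmetic is done with
:class:`fractions.Fraction`, so converting back and forth is the identity in
exact mode and conversions of integer multiples are exact in float mode. The
CO2:C factor is exactly 44/12, never a decimal approximation.
"""

from __future__ import annotations

from fractions import Fraction

from .errors import UFCarbonError

# factor such that value[to] = value[from] * factor
_FACTORS: dict[tuple[str, str], Fraction] = {
    ("km2", "ha"): Fraction(100),
    ("t", "kt"): Fraction(1, 1000),
    ("t_c", "t_co2"): Fraction(44, 12),
}
# aliases accepted on input
_ALIASES = {
    "km^2": "km2",
    "hectare": "ha",
    "tonnes": "t",
    "tc": "t_c",
    "tco2": "t_co2",
    "t c": "t_c",
    "t co2": "t_co2",
}

for (a, b), f in list(_FACTORS.items()):
    _FACTORS[(b, a)] = 1 / f


def _canon(unit: str) -> str:
    u = unit.strip().lower()
    return _ALIASES.get(u, u)


def conversion_factor(from_unit: str, to_unit: str) -> Fraction:
    """The exact rational factor for a supported unit pair."""
    key = (_canon(from_unit), _canon(to_unit))
    if key[0] == key[1]:
        return Fraction(1)
    try:
        return _FACTORS[key]
    except KeyError:
        raise UFCarbonError(
            f"unsupported unit conversion: {from_unit!r} -> {to_unit!r}"
        ) from None


def convert_units(value, from_unit: str, to_unit: str, *, exact: bool = False):
    """Convert ``value`` between supported units.

    With ``exact=True`` the result is returned as a :class:`~fractions.Fraction`
    (round-trip identity guaranteed); otherwise a float.
    """
    factor = conversion_factor(from_unit, to_unit)
    result = Fraction(value) * factor
    return result if exact else float(result)
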