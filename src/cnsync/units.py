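"""Unit handling for release curves.

Only the conversions that are well defined without extra chemistry are
registered: ingredient-level glucose is reported per 100 g sample while
diet-level work uses g/kg dry matter, a pure factor of 10.  Amount units
such as mmol/kg cannot be converted to mass units without a molar mass,
so those pairs raise.
"""

from __future__ import annotations

GLUCOSE_INGREDIENT_UNIT = "g/100g"
GLUCOSE_DIET_UNIT = "g/kg"
NITROGEN_UNIT = "g/kg"
AMINO_ACID_UNIT = "mmol/kg"

KNOWN_UNITS = frozenset({"g/100g", "g/kg", "mmol/kg"})

# (numerator, denominator) so that inverse conversions divide instead of
# multiplying by an inexact reciprocal: a round trip is then bit-exact.
_RATIOS: dict[tuple[str, str], tuple[int, int]] = {
    ("g/100g", "g/kg"): (10, 1),
    ("g/kg", "g/100g"): (1, 10),
}


class UnitConversionError(ValueError):
    """Raised when no conversion is defined between two units."""


def normalize_unit(unit: str) -> str:
    return unit.replace(" ", "")


def conversion_factor(source: str, target: str) -> float:
    """Multiplicative factor taking amounts in ``source`` to ``target``.

    Raises
    ------
    UnitConversionError
        If the pair has no registered conversion (e.g. mmol/kg to g/kg).
    """
    num, den = conversion_ratio(source, target)
    return num / den


def conversion_ratio(source: str, target: str) -> tuple[int, int]:
    """Conversion as an exact integer ratio ``(numerator, denominator)``."""
    src, dst = normalize_unit(source), normalize_unit(target)
    if src == dst:
        return (1, 1)
    try:
        return _RATIOS[(src, dst)]
    except KeyError:
        raise UnitConversionError(
            f"no conversion defined from {source!r} to {target!r}"
        ) from None
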