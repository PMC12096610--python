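"""Formulation logic for the starch-gradient diet panel.

The five experimental diets replace waxy maize starch (rapidly digested,
nearly pure amylopectin) with high-amylose maize starch (slowly
digested) in equal steps while every other ingredient — a fixed protein
mix, oil, minerals, and the 0.3% chromic oxide marker — stays constant,
so the panel spans a gradient in glucose-release rate at a constant
nutrient specification.  A nitrogen-free diet, used only to measure
basal endogenous amino-acid losses, is completed to 100% with normal
maize starch.

Inclusions are carried as exact two-decimal percentages (``Decimal``)
so sum-to-100 checks do not accumulate float drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

TWO_DP = Decimal("0.01")
MARKER = "Cr2O3"
MARKER_LEVEL = Decimal("0.30")
SUM_TOLERANCE = Decimal("0.01")

DIET_IDS = ("RGR_HGR", "MRGR_MHGR", "MGR_MGR", "MSGR_MLGR", "SGR_LGR")

#: Non-starch ingredients shared by the five experimental diets (%, as fed).
EXPERIMENTAL_FIXED: dict[str, Decimal] = {
    "Isolated soybean protein": Decimal("2.05"),
    "Casein": Decimal("14.38"),
    "Whey protein isolate": Decimal("2.72"),
    "Soybean oil": Decimal("3.00"),
    "Cellulose acetate": Decimal("4.00"),
    "Limestone": Decimal("0.50"),
    "Dicalcium phosphate": Decimal("2.50"),
    MARKER: MARKER_LEVEL,
    "NaCl": Decimal("0.45"),
    "K2CO3": Decimal("0.30"),
    "MgO": Decimal("0.10"),
    "Vitamin trace-mineral premix": Decimal("0.50"),
}

#: Non-starch ingredients of the nitrogen-free diet (no protein sources).
NITROGEN_FREE_FIXED: dict[str, Decimal] = {
    "Soybean oil": Decimal("3.00"),
    "Cellulose acetate": Decimal("4.00"),
    "Limestone": Decimal("0.50"),
    "Dicalcium phosphate": Decimal("2.50"),
    MARKER: MARKER_LEVEL,
    "NaCl": Decimal("0.45"),
    "K2CO3": Decimal("0.30"),
    "MgO": Decimal("0.10"),
    "Vitamin trace-mineral premix": Decimal("0.50"),
}


class DesignError(ValueError):
    """Invalid formulation request."""


def as_percent(value) -> Decimal:
    """Coerce to an exact two-decimal percentage."""
    return Decimal(str(value)).quantize(TWO_DP, rounding=ROUND_HALF_UP)


@dataclass
class DietSpec:
    """Ingredient -> inclusion map (%, as-fed) with marker metadata."""

    diet_id: str
    ingredients: dict[str, Decimal]
    marker_ingredient: str = MARKER
    marker_level: Decimal = MARKER_LEVEL
    nitrogen_free: bool = False

    def total(self) -> Decimal:
        return sum(self.ingredients.values(), Decimal("0"))


@dataclass
class ValidationReport:
    diet_id: str
    passed: bool
    issues: list[str] = field(default_factory=list)


def substitution_gradient(total: float, n_levels: int
                          ) -> list[tuple[Decimal, Decimal]]:
    """Equally spaced (base, substitute) starch pairs summing to ``total``.

    Level i (0-indexed) substitutes ``total * i / (n_levels - 1)`` percent
    of the slowly digested starch for the base starch, rounded to two
    decimals; the base takes the exact remainder so every pair conserves
    the total.
    """
    if n_levels < 2:
        raise DesignError("a gradient needs at least two levels")
    total_d = as_percent(total)
    if not total_d > 0:
        raise DesignError("total starch inclusion must be positive")
    pairs = []
    for i in range(n_levels):
        substitute = as_percent(total_d * i / (n_levels - 1))
        pairs.append((total_d - substitute, substitute))
    return pairs


def complete_formula(fixed: Mapping[str, float], filler_name: str, *,
                     diet_id: str = "NF", nitrogen_free: bool = True,
                     marker_ingredient: str = MARKER,
                     marker_level: Decimal = MARKER_LEVEL) -> DietSpec:
    """Complete a partial formula to 100% with a single filler ingredient."""
    ingredients = {name: as_percent(pct) for name, pct in fixed.items()}
    subtotal = sum(ingredients.values(), Decimal("0"))
    if subtotal >= 100:
        raise DesignError(
            f"fixed ingredients already sum to {subtotal}%; nothing to fill"
        )
    ingredients[filler_name] = (Decimal("100") - subtotal).quantize(TWO_DP)
    return DietSpec(diet_id=diet_id, ingredients=ingredients,
                    marker_ingredient=marker_ingredient,
                    marker_level=marker_level, nitrogen_free=nitrogen_free)


def validate_diet(spec: DietSpec) -> ValidationReport:
    """Check sum-to-100, non-negativity and marker presence at its level."""
    issues = []
    for name, pct in spec.ingredients.items():
        if pct < 0:
            issues.append(f"negative inclusion for {name!r} ({pct}%)")
    total = spec.total()
    if abs(total - Decimal("100")) > SUM_TOLERANCE:
        issues.append(f"inclusions sum to {total}%, not 100 ± {SUM_TOLERANCE}")
    marker_pct = spec.ingredients.get(spec.marker_ingredient)
    if marker_pct is None:
        issues.append(f"marker absent: {spec.marker_ingredient!r} not included")
    elif marker_pct != spec.marker_level:
        issues.append(
            f"marker {spec.marker_ingredient!r} at {marker_pct}%, expected "
            f"{spec.marker_level}%"
        )
    return ValidationReport(diet_id=spec.diet_id, passed=not issues,
                            issues=issues)


def gradient_diet_specs(base_starch: str = "Waxy maize starch",
                        substitute_starch: str = "High amylose maize starch",
                        fixed: Mapping[str, Decimal] | None = None,
                        diet_ids: tuple[str, ...] = DIET_IDS
                        ) -> list[DietSpec]:
    """The experimental panel: fixed mix plus the starch gradient.

    The total starch inclusion is whatever the fixed ingredients leave
    free, split between the rapidly digested base and the slowly
    digested substitute in equal steps across the diets.
    """
    fixed = dict(EXPERIMENTAL_FIXED if fixed is None else fixed)
    subtotal = sum(fixed.values(), Decimal("0"))
    if subtotal >= 100:
        raise DesignError("fixed ingredients leave no room for starch")
    total_starch = Decimal("100") - subtotal
    pairs = substitution_gradient(total_starch, len(diet_ids))
    specs = []
    for diet_id, (base_pct, sub_pct) in zip(diet_ids, pairs):
        ingredients = dict(fixed)
        if base_pct > 0:
            ingredients[base_starch] = base_pct
        if sub_pct > 0:
            ingredients[substitute_starch] = sub_pct
        specs.append(DietSpec(diet_id=diet_id, ingredients=ingredients))
    return specs


def nitrogen_free_spec(filler_name: str = "Normal maize starch") -> DietSpec:
    """The nitrogen-free diet, completed with normal maize starch."""
    return complete_formula(NITROGEN_FREE_FIXED, filler_name, diet_id="NF",
                            nitrogen_free=True)
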