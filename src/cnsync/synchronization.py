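"""Carbon-nitrogen release synchronization indices and diet classes.

During simulated digestion all diets release glucose, soluble nitrogen
and total amino acids fastest in the first 20 min of the intestinal
phase, so synchronization is scored over that common 0-20 min window.
For a diet d with window release rates K_Glucose (g/kg/min),
K_Nitrogen (g/kg/min) and K_AA (mmol/kg/min), and reference rates
K_GlucoseR, K_NitrogenR, K_AAR defined as the averages of the per-diet
rates across all diets in the panel, four indices are computed:

    Relative G/N  = (K_Glucose / K_GlucoseR) / (K_Nitrogen / K_NitrogenR)
    Relative G/AA = (K_Glucose / K_GlucoseR) / (K_AA / K_AAR)
    G/N           = K_Glucose / K_Nitrogen          (g/g)
    G/AA          = K_Glucose / K_AA                (g/mmol)

The relative indices compare each diet's carbon release against its
nitrogen release after normalizing both to the panel average, so a value
near 1 means carbon and nitrogen are released in step with each other
(relative to the panel); the absolute ratios expose the raw supply
balance.  Diets are classified on Relative G/AA: within a configurable
band around 1 they are synchronized (``Syn``); above it they show a
relative glucose excess / nitrogen shortfall (``Asyn_C``); below it a
relative nitrogen excess / glucose shortfall (``Asyn_N``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .kinetics import ReleaseCurve, interval_rate
from .units import AMINO_ACID_UNIT, GLUCOSE_DIET_UNIT, NITROGEN_UNIT

#: Intestinal-phase window (minutes) over which the indices are defined.
DEFAULT_WINDOW = (0.0, 20.0)

#: Classification band for Relative G/AA: [lower, upper] -> Syn.
DEFAULT_LOWER = 0.75
DEFAULT_UPPER = 1.50

SYNC_LABELS = ("Syn", "Asyn_C", "Asyn_N")

#: Required units per nutrient for diet-level synchronization work.
REQUIRED_UNITS = {
    "glucose": GLUCOSE_DIET_UNIT,
    "soluble_nitrogen": NITROGEN_UNIT,
    "total_amino_acids": AMINO_ACID_UNIT,
}


class SyncError(ValueError):
    """Invalid input to a synchronization computation."""


@dataclass(frozen=True)
class SyncContext:
    """Window plus panel reference rates shared by all diets."""

    window: tuple[float, float]
    k_glucose_ref: float
    k_nitrogen_ref: float
    k_aa_ref: float

    def __post_init__(self):
        if not (self.k_glucose_ref > 0 and self.k_nitrogen_ref > 0
                and self.k_aa_ref > 0):
            raise SyncError("all three reference rates must be positive")


@dataclass(frozen=True)
class SyncIndices:
    """The four synchronization indices for one diet (or one replicate)."""

    diet_id: str
    window: tuple[float, float]
    rel_gn: float
    rel_gaa: float
    gn: float
    gaa: float


@dataclass(frozen=True)
class SyncClass:
    label: str
    lower: float
    upper: float


def reference_rates(per_diet_rates: Mapping[str, float]) -> float:
    """Arithmetic mean of per-diet rates — the panel reference rate."""
    if len(per_diet_rates) < 2:
        raise SyncError("reference rate needs at least two diets")
    return float(np.mean(list(per_diet_rates.values())))


def build_context(per_diet_rates: Mapping[str, Mapping[str, float]],
                  window: tuple[float, float] = DEFAULT_WINDOW) -> SyncContext:
    """Reference rates from a mapping diet -> nutrient -> mean window rate."""
    refs = {}
    for nutrient in REQUIRED_UNITS:
        per_diet = {}
        for diet, rates in per_diet_rates.items():
            if nutrient not in rates:
                raise SyncError(f"diet {diet!r} is missing a {nutrient} rate")
            per_diet[diet] = rates[nutrient]
        refs[nutrient] = reference_rates(per_diet)
    return SyncContext(
        window=tuple(window),
        k_glucose_ref=refs["glucose"],
        k_nitrogen_ref=refs["soluble_nitrogen"],
        k_aa_ref=refs["total_amino_acids"],
    )


def sync_indices(diet_id: str, k_glucose: float, k_nitrogen: float,
                 k_aa: float, context: SyncContext) -> SyncIndices:
    """Compute the four indices for one diet against a panel context.

    ``k_glucose`` may be zero (a glucose-free diet scores 0 on every
    index) but the nitrogen and amino-acid rates must be positive; zero
    or negative denominators are reported as errors with the advice to
    widen the rate window rather than silently producing infinities.
    """
    if k_glucose < 0:
        raise SyncError(
            f"negative glucose rate for diet {diet_id!r}; widen the window "
            "so the interval captures net release"
        )
    for name, k in (("soluble nitrogen", k_nitrogen), ("amino acid", k_aa)):
        if k <= 0:
            raise SyncError(
                f"{name} rate for diet {diet_id!r} is {k:g}; the indices are "
                "undefined — widen the window so the rate is positive"
            )
    rel_g = k_glucose / context.k_glucose_ref
    return SyncIndices(
        diet_id=diet_id,
        window=context.window,
        rel_gn=rel_g / (k_nitrogen / context.k_nitrogen_ref),
        rel_gaa=rel_g / (k_aa / context.k_aa_ref),
        gn=k_glucose / k_nitrogen,
        gaa=k_glucose / k_aa,
    )


def classify(indices: "SyncIndices | float", lower: float = DEFAULT_LOWER,
             upper: float = DEFAULT_UPPER) -> SyncClass:
    """Label a diet from its Relative G/AA (closed band => ``Syn``)."""
    if lower >= upper:
        raise SyncError(f"lower bound {lower} must be below upper bound {upper}")
    rel_gaa = indices.rel_gaa if isinstance(indices, SyncIndices) else float(indices)
    if not np.isfinite(rel_gaa):
        raise SyncError("Relative G/AA must be finite to classify")
    if rel_gaa > upper:
        label = "Asyn_C"
    elif rel_gaa < lower:
        label = "Asyn_N"
    else:
        label = "Syn"
    return SyncClass(label=label, lower=lower, upper=upper)


def replicate_window_rates(curves: Iterable[ReleaseCurve],
                           window: tuple[float, float] = DEFAULT_WINDOW,
                           ) -> pd.DataFrame:
    """Per-replicate intestinal window rates for every curve.

    Returns a frame with columns diet, nutrient, replicate, rate.  Units
    are checked against the diet-level conventions (glucose g/kg,
    soluble nitrogen g/kg, total amino acids mmol/kg).
    """
    t1, t2 = window
    rows = []
    for curve in curves:
        expected = REQUIRED_UNITS.get(curve.nutrient)
        if expected is None:
            raise SyncError(f"unexpected nutrient {curve.nutrient!r}")
        if curve.unit != expected:
            raise SyncError(
                f"{curve.nutrient} curves must be in {expected}, got "
                f"{curve.unit!r} for diet {curve.substrate_id!r}"
            )
        rate = interval_rate(curve, t1, t2, phase="intestinal",
                             warn_negative=False)
        rows.append({
            "diet": curve.substrate_id,
            "nutrient": curve.nutrient,
            "replicate": curve.replicate,
            "rate": rate,
        })
    return pd.DataFrame(rows)


def sync_table(curves: Sequence[ReleaseCurve],
               window: tuple[float, float] = DEFAULT_WINDOW,
               lower: float = DEFAULT_LOWER, upper: float = DEFAULT_UPPER, *,
               reference: str = "diet_means",
               letters: bool = True) -> pd.DataFrame:
    """Per-diet mean ± SEM of all four indices, letters and class labels.

    Replicate indices are computed against one fixed context whose
    reference rates are, by default, the averages of the per-diet mean
    rates (``reference='diet_means'``; ``'pooled'`` averages every
    replicate value instead — identical when group sizes are equal).
    Tukey letters are attached to the Relative G/AA and G/AA columns.
    """
    if reference not in ("diet_means", "pooled"):
        raise SyncError(f"unknown reference mode {reference!r}")
    rates = replicate_window_rates(curves, window)
    if rates.empty:
        raise SyncError("no curves supplied")
    diets = list(dict.fromkeys(rates["diet"]))

    per_diet: dict[str, dict[str, float]] = {}
    for diet in diets:
        sub = rates[rates["diet"] == diet]
        nutrient_means = {}
        for nutrient in REQUIRED_UNITS:
            vals = sub.loc[sub["nutrient"] == nutrient, "rate"]
            if vals.empty:
                raise SyncError(f"diet {diet!r} is missing {nutrient} curves")
            nutrient_means[nutrient] = float(vals.mean())
        per_diet[diet] = nutrient_means

    if reference == "diet_means":
        context = build_context(per_diet, window)
    else:
        context = SyncContext(
            window=tuple(window),
            k_glucose_ref=float(
                rates.loc[rates["nutrient"] == "glucose", "rate"].mean()),
            k_nitrogen_ref=float(
                rates.loc[rates["nutrient"] == "soluble_nitrogen", "rate"].mean()),
            k_aa_ref=float(
                rates.loc[rates["nutrient"] == "total_amino_acids", "rate"].mean()),
        )

    # pair replicates across nutrients by replicate number within a diet
    per_rep: dict[str, list[SyncIndices]] = {d: [] for d in diets}
    wide = rates.pivot_table(index=["diet", "replicate"], columns="nutrient",
                             values="rate")
    for (diet, rep), row in wide.iterrows():
        if row.isna().any():
            missing = row.index[row.isna()].tolist()
            raise SyncError(
                f"diet {diet!r} replicate {rep} is missing {missing} curves"
            )
        per_rep[diet].append(sync_indices(
            diet, row["glucose"], row["soluble_nitrogen"],
            row["total_amino_acids"], context,
        ))

    index_cols = ("rel_gn", "rel_gaa", "gn", "gaa")
    records = []
    for diet in diets:
        reps = per_rep[diet]
        if len(reps) < 2:
            raise SyncError(f"diet {diet!r} needs at least two replicates")
        rec: dict[str, object] = {"diet": diet}
        for col in index_cols:
            vals = [getattr(ix, col) for ix in reps]
            rec[f"{col}_mean"], rec[f"{col}_sem"] = stats.mean_sem(vals)
        rec["class"] = classify(rec["rel_gaa_mean"], lower, upper).label
        records.append(rec)
    table = pd.DataFrame(records)

    for col in ("rel_gaa", "gaa"):
        if letters:
            grouped = {d: [getattr(ix, col) for ix in per_rep[d]] for d in diets}
            res = stats.group_compare(grouped, "anova_tukey")
            table[f"letters_{col}"] = [res.letters[d] for d in diets]
        else:
            table[f"letters_{col}"] = ""

    ordered = ["diet"]
    for col in index_cols:
        ordered += [f"{col}_mean", f"{col}_sem"]
    ordered += ["letters_rel_gaa", "letters_gaa", "class"]
    return table[ordered]
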