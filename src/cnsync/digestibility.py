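"""Marker-based ileal digestibility and total-tract balance calculations.

Chromic oxide (0.3% Cr2O3) is an indigestible marker: the ratio of its
concentration in the diet to its concentration in ileal digesta scales
nutrient flows without needing total collection at the ileum.  For an
amino acid (or crude protein) with concentrations in g/kg dry matter,

    AID = [1 - (AA_digesta / AA_diet) * (Cr_diet / Cr_digesta)] * 100
    IAA = AA_digesta * (Cr_diet / Cr_digesta)          (nitrogen-free diet)
    SID = AID + (IAA / AA_diet) * 100

where IAA, the basal ileal endogenous loss in g per kg dry-matter
intake, is measured in animals fed a nitrogen-free diet and is the only
correction separating standardized (SID) from apparent (AID) ileal
digestibility.  Total-tract digestibility and the balance fractions use
whole amounts collected over the balance days:

    ATTD = (intake - fecal) / intake * 100

with the complementary excretion fractions (fecal energy / energy
intake, etc.) summing with ATTD to exactly 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats


class DigestibilityError(ValueError):
    """Invalid input to a digestibility or balance computation."""


class DigestibilityWarning(UserWarning):
    """Unusual but admissible value (negative AID, fecal > intake)."""


@dataclass
class DietAssay:
    """Analyzed composition of one diet, per kg dry matter."""

    diet_id: str
    amino_acids: dict[str, float]       # g/kg DM per amino acid
    crude_protein: float                # g/kg DM
    chromium: float                     # g/kg DM
    gross_energy: float = 0.0           # MJ/kg DM

    def __post_init__(self):
        if not self.chromium > 0:
            raise DigestibilityError(
                f"diet {self.diet_id!r}: chromium concentration must be positive"
            )
        for aa, conc in self.amino_acids.items():
            if conc < 0:
                raise DigestibilityError(
                    f"diet {self.diet_id!r}: negative {aa} concentration"
                )


@dataclass
class DigestaAssay:
    """Analyzed ileal digesta of one animal, per kg dry matter."""

    animal_id: str
    diet_id: str
    amino_acids: dict[str, float]       # g/kg DM
    chromium: float                     # g/kg DM
    crude_protein: float = 0.0          # g/kg DM

    def __post_init__(self):
        if not self.chromium > 0:
            raise DigestibilityError(
                f"animal {self.animal_id!r}: digesta chromium must be positive"
            )


@dataclass
class EndogenousLosses:
    """Basal ileal endogenous losses, g per kg dry-matter intake."""

    values: dict[str, float]
    n_animals: int = 0

    def __post_init__(self):
        for aa, v in self.values.items():
            if v < 0:
                raise DigestibilityError(f"negative endogenous loss for {aa}")


@dataclass
class BalanceRecord:
    """Per-animal intake/output amounts over the balance period."""

    animal_id: str
    diet_id: str
    intake_n: float        # g/d
    fecal_n: float         # g/d
    urine_n: float         # g/d
    intake_ge: float       # MJ/d
    fecal_ge: float        # MJ/d
    urine_ge: float        # MJ/d
    bw_start: float        # kg
    bw_end: float          # kg
    days: float
    feed_total: float      # kg over the period

    def __post_init__(self):
        for name in ("intake_n", "fecal_n", "urine_n", "intake_ge",
                     "fecal_ge", "urine_ge", "bw_start", "feed_total"):
            if getattr(self, name) < 0:
                raise DigestibilityError(f"{name} must be non-negative")
        if self.bw_end < 0:
            raise DigestibilityError("final body weight must be non-negative")
        if not self.days > 0:
            raise DigestibilityError("days on test must be positive")


def attd(intake: float, fecal: float) -> float:
    """Apparent total-tract digestibility, percent."""
    if not intake > 0:
        raise DigestibilityError("intake must be positive")
    if fecal < 0:
        raise DigestibilityError("fecal output must be non-negative")
    if fecal > intake:
        warnings.warn(
            f"fecal output {fecal:g} exceeds intake {intake:g}; ATTD is negative",
            DigestibilityWarning, stacklevel=2,
        )
    return (intake - fecal) / intake * 100.0


def aid(aa_digesta: float, aa_diet: float, cr_diet: float,
        cr_digesta: float) -> float:
    """Apparent ileal digestibility of one analyte, percent.

    ``aa_diet`` must be positive; for the nitrogen-free diet use
    :func:`basal_endogenous_loss` instead.  Negative values (possible in
    low-protein assays) are returned with a warning, not truncated.
    """
    if not aa_diet > 0:
        raise DigestibilityError(
            "dietary concentration must be positive; for nitrogen-free-diet "
            "digesta use basal_endogenous_loss"
        )
    if not cr_diet > 0 or not cr_digesta > 0:
        raise DigestibilityError("chromium concentrations must be positive")
    if aa_digesta < 0:
        raise DigestibilityError("digesta concentration must be non-negative")
    value = (1.0 - (aa_digesta / aa_diet) * (cr_diet / cr_digesta)) * 100.0
    if value < 0:
        warnings.warn(
            f"negative AID ({value:.2f}%) — reported unchanged",
            DigestibilityWarning, stacklevel=2,
        )
    return value


def basal_endogenous_loss(nf_digesta: Sequence[DigestaAssay],
                          nf_diet: DietAssay, *,
                          agg: str = "mean") -> EndogenousLosses:
    """Basal endogenous losses from nitrogen-free-fed animals.

    The per-animal loss for each amino acid is
    ``AA_digesta * (Cr_diet / Cr_digesta)``; losses are then pooled
    across animals with the arithmetic mean (``agg='median'`` for a
    robust alternative).
    """
    if not nf_digesta:
        raise DigestibilityError("no nitrogen-free digesta assays supplied")
    if agg not in ("mean", "median"):
        raise DigestibilityError(f"unknown aggregation {agg!r}")
    for assay in nf_digesta:
        if assay.diet_id != nf_diet.diet_id:
            raise DigestibilityError(
                f"animal {assay.animal_id!r} was fed {assay.diet_id!r}, not "
                f"the nitrogen-free diet {nf_diet.diet_id!r}"
            )
    aas = sorted({aa for assay in nf_digesta for aa in assay.amino_acids})
    pooled: dict[str, float] = {}
    fn = np.mean if agg == "mean" else np.median
    for aa in aas:
        per_animal = [
            assay.amino_acids.get(aa, 0.0) * (nf_diet.chromium / assay.chromium)
            for assay in nf_digesta
        ]
        pooled[aa] = float(fn(per_animal))
    return EndogenousLosses(values=pooled, n_animals=len(nf_digesta))


def sid(aid_pct: float, iaa: float, aa_diet: float) -> float:
    """Standardized ileal digestibility: AID corrected for basal losses."""
    if not aa_diet > 0:
        raise DigestibilityError("dietary concentration must be positive")
    if iaa < 0:
        raise DigestibilityError("endogenous loss must be non-negative")
    return aid_pct + (iaa / aa_diet) * 100.0


def balance_fractions(record: BalanceRecord) -> dict[str, float]:
    """Excretion fractions in percent of intake.

    Keys: ``fe_fige`` (fecal energy / energy intake), ``ue_fige``
    (urinary energy / energy intake), ``fn_fin`` (fecal nitrogen /
    nitrogen intake), ``un_fin`` (urinary nitrogen / nitrogen intake).
    ``fe_fige`` is the exact complement of the energy ATTD.
    """
    if not record.intake_ge > 0 or not record.intake_n > 0:
        raise DigestibilityError("intakes must be positive")
    return {
        "fe_fige": record.fecal_ge / record.intake_ge * 100.0,
        "ue_fige": record.urine_ge / record.intake_ge * 100.0,
        "fn_fin": record.fecal_n / record.intake_n * 100.0,
        "un_fin": record.urine_n / record.intake_n * 100.0,
    }


def growth_performance(record: BalanceRecord) -> dict[str, float]:
    """Average daily gain and feed intake (kg/d) over the test period."""
    return {
        "adg": (record.bw_end - record.bw_start) / record.days,
        "adfi": record.feed_total / record.days,
    }


def aid_sid_table(diet_assays: Mapping[str, DietAssay],
                  digesta_assays: Sequence[DigestaAssay],
                  nf_diet_id: str = "NF", *,
                  agg: str = "mean",
                  include_crude_protein: bool = True) -> pd.DataFrame:
    """Per-animal AID and SID for every amino acid (long format).

    Animals fed the nitrogen-free diet are used only to estimate the
    basal endogenous losses; every other animal contributes one row per
    amino acid with columns ``animal_id, diet_id, analyte, aid, sid``.
    Crude protein gets AID only (no basal-loss correction is defined
    for it here) unless its concentration is absent.
    """
    if nf_diet_id not in diet_assays:
        raise DigestibilityError(f"nitrogen-free diet {nf_diet_id!r} not supplied")
    nf_animals = [a for a in digesta_assays if a.diet_id == nf_diet_id]
    losses = basal_endogenous_loss(nf_animals, diet_assays[nf_diet_id], agg=agg)

    rows = []
    for assay in digesta_assays:
        if assay.diet_id == nf_diet_id:
            continue
        diet = diet_assays.get(assay.diet_id)
        if diet is None:
            raise DigestibilityError(
                f"no diet assay for diet {assay.diet_id!r} (animal "
                f"{assay.animal_id!r})"
            )
        for aa, conc_digesta in assay.amino_acids.items():
            conc_diet = diet.amino_acids.get(aa, 0.0)
            if conc_diet <= 0:
                raise DigestibilityError(
                    f"diet {diet.diet_id!r} has no {aa} but digesta of animal "
                    f"{assay.animal_id!r} does"
                )
            a = aid(conc_digesta, conc_diet, diet.chromium, assay.chromium)
            s = sid(a, losses.values.get(aa, 0.0), conc_diet)
            rows.append({"animal_id": assay.animal_id, "diet_id": assay.diet_id,
                         "analyte": aa, "aid": a, "sid": s})
        if include_crude_protein and diet.crude_protein > 0 \
                and assay.crude_protein > 0:
            a = aid(assay.crude_protein, diet.crude_protein, diet.chromium,
                    assay.chromium)
            rows.append({"animal_id": assay.animal_id, "diet_id": assay.diet_id,
                         "analyte": "crude_protein", "aid": a, "sid": np.nan})
    return pd.DataFrame(rows)


def balance_table(records: Sequence[BalanceRecord]) -> pd.DataFrame:
    """Per-animal ATTD, excretion fractions and growth metrics."""
    if not records:
        raise DigestibilityError("no balance records supplied")
    rows = []
    for rec in records:
        fractions = balance_fractions(rec)
        growth = growth_performance(rec)
        rows.append({
            "animal_id": rec.animal_id,
            "diet_id": rec.diet_id,
            "attd_ge": attd(rec.intake_ge, rec.fecal_ge),
            "attd_n": attd(rec.intake_n, rec.fecal_n),
            **fractions,
            **growth,
        })
    return pd.DataFrame(rows)


def summarize_by_diet(table: pd.DataFrame, *, group_col: str = "diet_id",
                      letters: bool = True,
                      metrics: Sequence[str] | None = None) -> pd.DataFrame:
    """Mean ± SEM per diet for each metric column, with Tukey letters."""
    if metrics is None:
        metrics = [c for c in table.columns
                   if c not in (group_col, "animal_id", "analyte")
                   and pd.api.types.is_numeric_dtype(table[c])]
    diets = list(dict.fromkeys(table[group_col]))
    out: list[dict[str, object]] = [{group_col: d} for d in diets]
    by_diet = {d: table[table[group_col] == d] for d in diets}
    for metric in metrics:
        grouped = {d: by_diet[d][metric].dropna().to_numpy() for d in diets}
        grouped = {d: v for d, v in grouped.items() if v.size >= 2}
        res = None
        if letters and len(grouped) >= 2:
            res = stats.group_compare(grouped, "anova_tukey")
        for rec, d in zip(out, diets):
            vals = by_diet[d][metric].dropna().to_numpy()
            if vals.size >= 2:
                m, s = stats.mean_sem(vals)
            else:
                m, s = (float(vals[0]) if vals.size else np.nan), np.nan
            rec[f"{metric}_mean"] = m
            rec[f"{metric}_sem"] = s
            rec[f"letters_{metric}"] = res.letters.get(d, "") if res else ""
    return pd.DataFrame(out)
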