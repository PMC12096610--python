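"""CSV readers and writers for the pipeline's tabular interfaces.

All files are plain UTF-8 CSV with a decimal point and a strict header:
an unexpected or missing column is an error, not a guess.

curves.csv        substrate_id, nutrient, replicate, phase, time_min,
                  cumulative, unit
rates.csv         substrate_id, nutrient, replicate, t1, t2, rate,
                  unit_per_min, flag_negative
diet_assay.csv    diet_id, analyte, value, unit
digesta_assay.csv animal_id, diet_id, analyte, value, unit
balance.csv       animal_id, diet_id, intake_n_g_d, fecal_n_g_d,
                  urine_n_g_d, intake_ge_mj_d, fecal_ge_mj_d,
                  urine_ge_mj_d, bw_start_kg, bw_end_kg, days,
                  feed_total_kg
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .digestibility import BalanceRecord, DietAssay, DigestaAssay
from .kinetics import RateSeries, ReleaseCurve

CURVE_COLUMNS = ["substrate_id", "nutrient", "replicate", "phase", "time_min",
                 "cumulative", "unit"]
RATE_COLUMNS = ["substrate_id", "nutrient", "replicate", "t1", "t2", "rate",
                "unit_per_min", "flag_negative"]
ASSAY_DIET_COLUMNS = ["diet_id", "analyte", "value", "unit"]
ASSAY_DIGESTA_COLUMNS = ["animal_id", "diet_id", "analyte", "value", "unit"]
BALANCE_COLUMNS = ["animal_id", "diet_id", "intake_n_g_d", "fecal_n_g_d",
                   "urine_n_g_d", "intake_ge_mj_d", "fecal_ge_mj_d",
                   "urine_ge_mj_d", "bw_start_kg", "bw_end_kg", "days",
                   "feed_total_kg"]

_PHASE_ORDER = {"gastric": 0, "intestinal": 1}


class FormatError(ValueError):
    """A file does not match its declared schema."""


def _check_columns(df: pd.DataFrame, expected: Sequence[str], path) -> None:
    if list(df.columns) != list(expected):
        raise FormatError(
            f"{path}: expected columns {list(expected)}, got {list(df.columns)}"
        )


def read_curves_csv(path) -> list[ReleaseCurve]:
    """Read long-format release curves, one curve per
    (substrate, nutrient, replicate) group, gastric samples first."""
    df = pd.read_csv(path, encoding="utf-8")
    _check_columns(df, CURVE_COLUMNS, path)
    curves = []
    for (substrate, nutrient, replicate), grp in df.groupby(
            ["substrate_id", "nutrient", "replicate"], sort=True):
        units = grp["unit"].unique()
        if len(units) != 1:
            raise FormatError(
                f"{path}: mixed units {units.tolist()} within curve "
                f"{substrate}/{nutrient}/rep {replicate}"
            )
        grp = grp.sort_values(
            ["phase", "time_min"],
            key=lambda s: s.map(_PHASE_ORDER) if s.name == "phase" else s,
        )
        curves.append(ReleaseCurve(
            substrate_id=str(substrate), nutrient=str(nutrient),
            replicate=int(replicate), phases=tuple(grp["phase"]),
            times=grp["time_min"].to_numpy(dtype=float),
            cumulative=grp["cumulative"].to_numpy(dtype=float),
            unit=str(units[0]),
        ))
    return curves


def curves_frame(curves: Iterable[ReleaseCurve]) -> pd.DataFrame:
    rows = []
    for c in curves:
        for phase, t, v in zip(c.phases, c.times, c.cumulative):
            rows.append({
                "substrate_id": c.substrate_id, "nutrient": c.nutrient,
                "replicate": c.replicate, "phase": phase, "time_min": t,
                "cumulative": v, "unit": c.unit,
            })
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def write_curves_csv(curves: Iterable[ReleaseCurve], path) -> None:
    curves_frame(curves).to_csv(path, index=False, lineterminator="\n")


def rates_frame(series: Iterable[RateSeries]) -> pd.DataFrame:
    rows = []
    for rs in series:
        for (t1, t2), rate in zip(rs.intervals, rs.rates):
            rows.append({
                "substrate_id": rs.substrate_id, "nutrient": rs.nutrient,
                "replicate": rs.replicate, "t1": t1, "t2": t2, "rate": rate,
                "unit_per_min": rs.unit_per_min,
                "flag_negative": bool(rate < 0),
            })
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def write_rates_csv(series: Iterable[RateSeries], path) -> None:
    rates_frame(series).to_csv(path, index=False, lineterminator="\n")


def _pivot_assay(grp: pd.DataFrame, path) -> tuple[dict[str, float], dict]:
    """Split analyte rows into amino acids vs. the named bulk analytes."""
    special = {}
    amino_acids = {}
    for _, row in grp.iterrows():
        analyte = str(row["analyte"])
        value = float(row["value"])
        if analyte in ("crude_protein", "chromium", "gross_energy"):
            special[analyte] = value
        else:
            amino_acids[analyte] = value
    if "chromium" not in special:
        raise FormatError(f"{path}: assay is missing a 'chromium' row")
    return amino_acids, special


def read_diet_assays(path) -> dict[str, DietAssay]:
    df = pd.read_csv(path, encoding="utf-8")
    _check_columns(df, ASSAY_DIET_COLUMNS, path)
    assays = {}
    for diet_id, grp in df.groupby("diet_id", sort=True):
        amino_acids, special = _pivot_assay(grp, path)
        assays[str(diet_id)] = DietAssay(
            diet_id=str(diet_id), amino_acids=amino_acids,
            crude_protein=special.get("crude_protein", 0.0),
            chromium=special["chromium"],
            gross_energy=special.get("gross_energy", 0.0),
        )
    return assays


def read_digesta_assays(path) -> list[DigestaAssay]:
    df = pd.read_csv(path, encoding="utf-8")
    _check_columns(df, ASSAY_DIGESTA_COLUMNS, path)
    assays = []
    for (animal_id, diet_id), grp in df.groupby(
            ["animal_id", "diet_id"], sort=True):
        amino_acids, special = _pivot_assay(grp, path)
        assays.append(DigestaAssay(
            animal_id=str(animal_id), diet_id=str(diet_id),
            amino_acids=amino_acids, chromium=special["chromium"],
            crude_protein=special.get("crude_protein", 0.0),
        ))
    return assays


def diet_assays_frame(assays: dict[str, DietAssay]) -> pd.DataFrame:
    rows = []
    for diet_id in sorted(assays):
        a = assays[diet_id]
        for aa in sorted(a.amino_acids):
            rows.append({"diet_id": diet_id, "analyte": aa,
                         "value": a.amino_acids[aa], "unit": "g/kg"})
        rows.append({"diet_id": diet_id, "analyte": "crude_protein",
                     "value": a.crude_protein, "unit": "g/kg"})
        rows.append({"diet_id": diet_id, "analyte": "chromium",
                     "value": a.chromium, "unit": "g/kg"})
        rows.append({"diet_id": diet_id, "analyte": "gross_energy",
                     "value": a.gross_energy, "unit": "MJ/kg"})
    return pd.DataFrame(rows, columns=ASSAY_DIET_COLUMNS)


def digesta_assays_frame(assays: Iterable[DigestaAssay]) -> pd.DataFrame:
    rows = []
    for a in assays:
        for aa in sorted(a.amino_acids):
            rows.append({"animal_id": a.animal_id, "diet_id": a.diet_id,
                         "analyte": aa, "value": a.amino_acids[aa],
                         "unit": "g/kg"})
        rows.append({"animal_id": a.animal_id, "diet_id": a.diet_id,
                     "analyte": "crude_protein", "value": a.crude_protein,
                     "unit": "g/kg"})
        rows.append({"animal_id": a.animal_id, "diet_id": a.diet_id,
                     "analyte": "chromium", "value": a.chromium,
                     "unit": "g/kg"})
    return pd.DataFrame(rows, columns=ASSAY_DIGESTA_COLUMNS)


def read_balance_records(path) -> list[BalanceRecord]:
    df = pd.read_csv(path, encoding="utf-8")
    _check_columns(df, BALANCE_COLUMNS, path)
    return [
        BalanceRecord(
            animal_id=str(row.animal_id), diet_id=str(row.diet_id),
            intake_n=row.intake_n_g_d, fecal_n=row.fecal_n_g_d,
            urine_n=row.urine_n_g_d, intake_ge=row.intake_ge_mj_d,
            fecal_ge=row.fecal_ge_mj_d, urine_ge=row.urine_ge_mj_d,
            bw_start=row.bw_start_kg, bw_end=row.bw_end_kg, days=row.days,
            feed_total=row.feed_total_kg,
        )
        for row in df.itertuples()
    ]


def balance_frame(records: Iterable[BalanceRecord]) -> pd.DataFrame:
    rows = [{
        "animal_id": r.animal_id, "diet_id": r.diet_id,
        "intake_n_g_d": r.intake_n, "fecal_n_g_d": r.fecal_n,
        "urine_n_g_d": r.urine_n, "intake_ge_mj_d": r.intake_ge,
        "fecal_ge_mj_d": r.fecal_ge, "urine_ge_mj_d": r.urine_ge,
        "bw_start_kg": r.bw_start, "bw_end_kg": r.bw_end, "days": r.days,
        "feed_total_kg": r.feed_total,
    } for r in records]
    return pd.DataFrame(rows, columns=BALANCE_COLUMNS)
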