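"""Cumulative nutrient-release time courses and interval release rates.

An in vitro digestion run proceeds in two successive phases — a gastric
phase (pepsin, pH 3.5, 120 min) followed by an intestinal phase
(pancreatin + amyloglucosidase, pH 6.8, 480 min).  Each phase is sampled
on its own clock: intestinal time 0 is the start of the intestinal
incubation, not minute 120 of the run.  A :class:`ReleaseCurve` stores
the cumulative amount of one nutrient (glucose, soluble nitrogen, or
total amino acids) released by one replicate of one substrate, with a
phase label per sampling time.

The release rate over an interval is the difference quotient of the
cumulative curve,

    K = (D_t2 - D_t1) / (t2 - t1),

computed between measured points only: the baseline at the interval
start is the measured value (amyloglucosidase is added at the start of
the intestinal phase, so D at intestinal time 0 need not be zero).
Replicate curves can fluctuate downward between adjacent time points at
low release amounts; negative rates are therefore retained and flagged,
never clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .units import conversion_ratio, normalize_unit

NUTRIENTS = ("glucose", "soluble_nitrogen", "total_amino_acids")
PHASES = ("gastric", "intestinal")

#: Sampling schedules used by the digestion protocol (minutes on each
#: phase's own clock).  Glucose is sampled in the intestinal phase only.
GASTRIC_SCHEDULE = (60.0, 120.0)
INTESTINAL_SCHEDULE = (0.0, 20.0, 60.0, 90.0, 120.0, 240.0, 360.0, 480.0)
GASTRIC_DURATION_MIN = 120.0


class CurveError(ValueError):
    """Structural problem with a release curve or a rate request."""


class NonMonotoneWarning(UserWarning):
    """Cumulative release decreased between adjacent time points."""


class NegativeRateWarning(UserWarning):
    """An interval release rate is negative (kept, not clipped)."""


@dataclass
class ReleaseCurve:
    """One substrate x nutrient x replicate cumulative release series.

    Parameters
    ----------
    substrate_id
        Feed ingredient or diet identifier.
    nutrient
        One of ``glucose``, ``soluble_nitrogen``, ``total_amino_acids``.
    replicate
        Positive replicate number within the substrate.
    phases
        Phase label (``gastric`` or ``intestinal``) per sampling time.
    times
        Sampling times in minutes, each on its phase's own clock.
    cumulative
        Cumulative amount released at each time, in ``unit``.
    unit
        Unit string shared by every point (e.g. ``g/kg``, ``mmol/kg``).
    """

    substrate_id: str
    nutrient: str
    replicate: int
    phases: tuple[str, ...]
    times: np.ndarray
    cumulative: np.ndarray
    unit: str

    def __post_init__(self) -> None:
        self.phases = tuple(self.phases)
        self.times = np.asarray(self.times, dtype=float)
        self.cumulative = np.asarray(self.cumulative, dtype=float)
        self.unit = normalize_unit(self.unit)

    def __len__(self) -> int:
        return self.times.size

    def phase_mask(self, phase: str) -> np.ndarray:
        if phase not in PHASES:
            raise CurveError(f"unknown phase {phase!r}; expected one of {PHASES}")
        return np.array([p == phase for p in self.phases], dtype=bool)

    def phase_times(self, phase: str) -> np.ndarray:
        return self.times[self.phase_mask(phase)]

    def phase_values(self, phase: str) -> np.ndarray:
        return self.cumulative[self.phase_mask(phase)]

    def value_at(self, t: float, phase: str = "intestinal", *,
                 interpolate: bool = False) -> float:
        """Cumulative amount at time ``t`` of ``phase``.

        By default ``t`` must be a sampled time; with ``interpolate=True``
        a linear interpolation between sampled neighbours is used (meant
        for simulator-generated dense grids, not for the measured
        protocol schedule).
        """
        tt = self.phase_times(phase)
        vv = self.phase_values(phase)
        if tt.size == 0:
            raise CurveError(
                f"curve {self.substrate_id}/{self.nutrient} has no "
                f"{phase}-phase samples"
            )
        hit = np.isclose(tt, t)
        if hit.any():
            return float(vv[np.argmax(hit)])
        if not interpolate:
            raise CurveError(
                f"time {t} min not sampled in the {phase} phase of "
                f"{self.substrate_id}/{self.nutrient} (sampled: {tt.tolist()}); "
                "pass interpolate=True to allow linear interpolation"
            )
        if not tt.min() <= t <= tt.max():
            raise CurveError(f"time {t} min outside sampled range of {phase} phase")
        return float(np.interp(t, tt, vv))


@dataclass
class RateSeries:
    """Interval release rates over consecutive sampled times of one phase."""

    substrate_id: str
    nutrient: str
    replicate: int
    phase: str
    intervals: tuple[tuple[float, float], ...]
    rates: np.ndarray
    unit_per_min: str

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        for t1, t2 in self.intervals:
            if not t2 > t1:
                raise CurveError(f"interval ({t1}, {t2}) is not increasing")

    def __len__(self) -> int:
        return self.rates.size

    @property
    def negative_flags(self) -> np.ndarray:
        return self.rates < 0


def validate_curve(curve: ReleaseCurve) -> tuple[ReleaseCurve, list[str]]:
    """Check a curve's structural invariants.

    Returns the curve unchanged plus a list of warnings, one per adjacent
    pair where the cumulative amount decreases (permitted but flagged).
    Negative amounts, unknown labels, duplicated or unordered times
    within a phase are hard errors.
    """
    if len(curve) == 0:
        raise CurveError("empty curve")
    if curve.nutrient not in NUTRIENTS:
        raise CurveError(
            f"unknown nutrient {curve.nutrient!r}; expected one of {NUTRIENTS}"
        )
    if curve.replicate < 1:
        raise CurveError("replicate must be a positive integer")
    if len(curve.phases) != len(curve) or curve.cumulative.size != len(curve):
        raise CurveError("phases, times and cumulative must be aligned")
    for p in curve.phases:
        if p not in PHASES:
            raise CurveError(f"unknown phase {p!r}")
    if np.any(curve.cumulative < 0):
        raise CurveError(
            f"negative cumulative amount in {curve.substrate_id}/{curve.nutrient}"
        )
    if np.any(curve.times < 0):
        raise CurveError("negative sampling time")

    warnings_out: list[str] = []
    for phase in PHASES:
        tt = curve.phase_times(phase)
        vv = curve.phase_values(phase)
        if tt.size and np.any(np.diff(tt) <= 0):
            raise CurveError(
                f"times not strictly increasing within the {phase} phase of "
                f"{curve.substrate_id}/{curve.nutrient}"
            )
        drops = np.flatnonzero(np.diff(vv) < 0)
        for i in drops:
            warnings_out.append(
                f"cumulative {curve.nutrient} decreases over "
                f"{phase} {tt[i]:g}-{tt[i + 1]:g} min in "
                f"{curve.substrate_id} rep {curve.replicate}"
            )
    return curve, warnings_out


def interval_rate(curve: ReleaseCurve, t1: float, t2: float, *,
                  phase: str = "intestinal", interpolate: bool = False,
                  warn_negative: bool = True) -> float:
    """Release rate K = (D_t2 - D_t1)/(t2 - t1) within one phase.

    Both endpoints must be sampled times of the same phase unless
    ``interpolate`` is set.  The rate may be negative when the replicate
    fluctuated downward; a :class:`NegativeRateWarning` is emitted and
    the value is returned unchanged.
    """
    if not t1 < t2:
        raise CurveError(f"interval endpoints must satisfy t1 < t2, got ({t1}, {t2})")
    d1 = curve.value_at(t1, phase, interpolate=interpolate)
    d2 = curve.value_at(t2, phase, interpolate=interpolate)
    k = (d2 - d1) / (t2 - t1)
    if k < 0 and warn_negative:
        warnings.warn(
            f"negative release rate {k:.4g} over {phase} {t1:g}-{t2:g} min "
            f"({curve.substrate_id}/{curve.nutrient} rep {curve.replicate})",
            NegativeRateWarning,
            stacklevel=2,
        )
    return k


def rate_series(curve: ReleaseCurve, grid: Sequence[float], *,
                phase: str = "intestinal", interpolate: bool = False) -> RateSeries:
    """One rate per consecutive pair of ``grid`` times, order preserved."""
    grid = [float(t) for t in grid]
    if len(grid) < 2:
        raise CurveError("grid needs at least two times")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise CurveError("grid must be strictly increasing")
    sampled = curve.phase_times(phase)
    if not interpolate:
        for t in grid:
            if not np.isclose(sampled, t).any():
                raise CurveError(
                    f"grid time {t:g} min not sampled in the {phase} phase of "
                    f"{curve.substrate_id}/{curve.nutrient}"
                )
    rates = [
        interval_rate(curve, a, b, phase=phase, interpolate=interpolate,
                      warn_negative=False)
        for a, b in zip(grid, grid[1:])
    ]
    return RateSeries(
        substrate_id=curve.substrate_id,
        nutrient=curve.nutrient,
        replicate=curve.replicate,
        phase=phase,
        intervals=tuple(zip(grid, grid[1:])),
        rates=np.array(rates),
        unit_per_min=f"{curve.unit}/min",
    )


@dataclass
class CurveSummary:
    """Replicate mean curve with pointwise SEM (sd/sqrt(n), sample sd)."""

    curve: ReleaseCurve
    sem: np.ndarray
    n: int


def summarize_replicates(curves: Sequence[ReleaseCurve]) -> CurveSummary:
    """Pointwise mean and SEM across replicate curves on a shared grid."""
    if len(curves) < 2:
        raise CurveError("need at least two replicate curves to summarize")
    first = curves[0]
    for c in curves[1:]:
        if (c.substrate_id, c.nutrient) != (first.substrate_id, first.nutrient):
            raise CurveError("replicates must share substrate and nutrient")
        if c.unit != first.unit:
            raise CurveError("replicates must share one unit")
        if c.phases != first.phases or not np.array_equal(c.times, first.times):
            raise CurveError("replicates must share one sampling grid")
    stack = np.vstack([c.cumulative for c in curves])
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(curves))
    mean_curve = replace(first, replicate=0, cumulative=mean)
    return CurveSummary(curve=mean_curve, sem=sem, n=len(curves))


def convert_units(curve: ReleaseCurve, target_unit: str) -> ReleaseCurve:
    """Rescale a curve to ``target_unit`` (round-trip exact)."""
    num, den = conversion_ratio(curve.unit, target_unit)
    return replace(
        curve,
        cumulative=curve.cumulative * num / den,
        unit=normalize_unit(target_unit),
    )
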