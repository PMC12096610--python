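"""Synthetic digestion curves, diet panels and a virtual balance trial.

The analysis pipeline never needs real assay data: this module generates
every input it reads, with known ground truth, so each stage can be
exercised end to end.

Release curves use saturating first-order kinetics as a stand-in shape,

    D(t) = A * (1 - exp(-k * max(0, t - lag))),

with amplitude ``A`` in curve units, rate constant ``k`` per minute and
an optional lag.  This reproduces the qualitative features of measured
curves — rapid early release, a plateau, most glucose released within
the first ~120 intestinal minutes — without claiming a mechanistic fit.
Replicate noise is additive Gaussian on each sampled cumulative value,
clipped at zero, which deliberately permits non-monotone replicates at
low release amounts (the same fluctuations flagged by curve
validation).  Glucose appears only in the intestinal phase (no
amyloglucosidase acts earlier); soluble nitrogen and amino acids release
in both phases, and their intestinal cumulative values carry the
gastric-phase amount forward as a baseline offset.

All randomness flows from one integer seed through deterministically
spawned sub-streams, so identical configurations give identical output.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .diet_design import DIET_IDS
from .digestibility import BalanceRecord, DietAssay, DigestaAssay
from .kinetics import (
    GASTRIC_DURATION_MIN,
    GASTRIC_SCHEDULE,
    INTESTINAL_SCHEDULE,
    ReleaseCurve,
)
from .units import AMINO_ACID_UNIT, GLUCOSE_DIET_UNIT, NITROGEN_UNIT


class SimulationError(ValueError):
    """Invalid simulator configuration."""


@dataclass(frozen=True)
class KineticParams:
    """First-order release parameters for one substrate x nutrient x phase.

    ``amplitude`` is the asymptotic cumulative release in curve units,
    ``rate`` the first-order constant per minute, ``lag`` a delay in
    minutes before release starts, and ``sigma`` the additive replicate
    noise s.d. in curve units.
    """

    amplitude: float
    rate: float
    lag: float = 0.0
    sigma: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0 or self.rate < 0 or self.lag < 0 or self.sigma < 0:
            raise SimulationError("kinetic parameters must be non-negative")

    def cumulative(self, t: np.ndarray | float) -> np.ndarray | float:
        tt = np.maximum(0.0, np.asarray(t, dtype=float) - self.lag)
        return self.amplitude * -np.expm1(-self.rate * tt)


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    seq = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in seq.spawn(n)]


def simulate_release_curve(params: Mapping[str, KineticParams],
                           schedule: Mapping[str, Sequence[float]],
                           substrate_id: str, nutrient: str, unit: str, *,
                           n_replicates: int = 3,
                           seed: int = 0) -> list[ReleaseCurve]:
    """Simulate replicate curves for one substrate and nutrient.

    ``params`` and ``schedule`` map phase name to kinetics and sampling
    times.  If both phases are present, the intestinal cumulative values
    include the noiseless gastric amount at the end of the gastric phase
    as a baseline offset (the assays measure total release so far).
    """
    if not schedule or all(len(v) == 0 for v in schedule.values()):
        raise SimulationError("empty sampling schedule")
    for phase in schedule:
        if phase not in params:
            raise SimulationError(f"no kinetic parameters for phase {phase!r}")

    gastric_offset = 0.0
    if "gastric" in params and "intestinal" in schedule:
        gastric_offset = float(params["gastric"].cumulative(GASTRIC_DURATION_MIN))

    phases: list[str] = []
    times: list[float] = []
    noiseless: list[float] = []
    sigmas: list[float] = []
    for phase in ("gastric", "intestinal"):
        if phase not in schedule:
            continue
        p = params[phase]
        for t in schedule[phase]:
            phases.append(phase)
            times.append(float(t))
            base = float(p.cumulative(t))
            if phase == "intestinal":
                base += gastric_offset
            noiseless.append(base)
            sigmas.append(p.sigma)

    base_arr = np.array(noiseless)
    sigma_arr = np.array(sigmas)
    curves = []
    for rep, rng in enumerate(_spawn_rngs(seed, n_replicates), start=1):
        values = base_arr + rng.normal(0.0, 1.0, base_arr.size) * sigma_arr
        curves.append(ReleaseCurve(
            substrate_id=substrate_id, nutrient=nutrient, replicate=rep,
            phases=tuple(phases), times=np.array(times),
            cumulative=np.clip(values, 0.0, None), unit=unit,
        ))
    return curves


# ---------------------------------------------------------------------------
# Diet panel
# ---------------------------------------------------------------------------

#: Default glucose kinetics at the two gradient endpoints (g/kg DM).
#: The rapid endpoint releases ~97% of its glucose within 120 intestinal
#: minutes; the slow endpoint is still rising at 480 min.
GLUCOSE_FAST = KineticParams(amplitude=450.0, rate=0.030)
GLUCOSE_SLOW = KineticParams(amplitude=280.0, rate=0.007)

#: Default soluble-nitrogen kinetics shared across diets (g/kg DM): the
#: protein mix is identical in every diet, so its release is too.
NITROGEN_DEFAULT = {
    "gastric": KineticParams(amplitude=5.0, rate=0.020),
    "intestinal": KineticParams(amplitude=9.0, rate=0.040),
}

#: Default total-amino-acid kinetics shared across diets (mmol/kg DM).
AA_DEFAULT = {
    "gastric": KineticParams(amplitude=18.0, rate=0.020),
    "intestinal": KineticParams(amplitude=45.0, rate=0.040),
}

PANEL_SCHEDULES = {
    "glucose": {"intestinal": INTESTINAL_SCHEDULE},
    "soluble_nitrogen": {"gastric": GASTRIC_SCHEDULE,
                         "intestinal": INTESTINAL_SCHEDULE},
    "total_amino_acids": {"gastric": GASTRIC_SCHEDULE,
                          "intestinal": INTESTINAL_SCHEDULE},
}

PANEL_UNITS = {
    "glucose": GLUCOSE_DIET_UNIT,
    "soluble_nitrogen": NITROGEN_UNIT,
    "total_amino_acids": AMINO_ACID_UNIT,
}


def _with_noise(p: KineticParams, noise_frac: float) -> KineticParams:
    return replace(p, sigma=noise_frac * p.amplitude)


def simulate_diet_panel(fractions: Sequence[float] = (1.0, 0.75, 0.5, 0.25, 0.0),
                        *,
                        glucose_fast: KineticParams = GLUCOSE_FAST,
                        glucose_slow: KineticParams = GLUCOSE_SLOW,
                        nitrogen=None, aa=None,
                        diet_ids: Sequence[str] = DIET_IDS,
                        n_replicates: int = 3,
                        noise_frac: float = 0.02,
                        seed: int = 0) -> list[ReleaseCurve]:
    """Simulate the 5-diet x 3-nutrient x replicate curve panel.

    ``fractions`` gives each diet's proportion of the rapidly digested
    (waxy) starch; glucose amplitude and rate are interpolated linearly
    between the slow and fast endpoints, so a higher waxy fraction means
    faster and larger glucose release.  ``nitrogen`` and ``aa`` may be a
    single phase->params mapping shared by every diet (the default: the
    protein mix is constant across the panel) or a sequence of per-diet
    mappings.  ``noise_frac`` scales the replicate noise s.d. as a
    fraction of each amplitude.
    """
    fractions = [float(f) for f in fractions]
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise SimulationError("waxy fractions must lie in [0, 1]")
    if len(fractions) != len(diet_ids):
        raise SimulationError("need one waxy fraction per diet id")
    if glucose_fast.amplitude < glucose_slow.amplitude:
        warnings.warn(
            "fast-endpoint glucose amplitude is below the slow endpoint; "
            "the panel ordering will be inverted", UserWarning, stacklevel=2,
        )
    nitrogen = NITROGEN_DEFAULT if nitrogen is None else nitrogen
    aa = AA_DEFAULT if aa is None else aa

    def per_diet(spec, i):
        if isinstance(spec, Mapping):
            return spec
        return spec[i]

    curves: list[ReleaseCurve] = []
    sub_seeds = np.random.SeedSequence(seed).generate_state(
        3 * len(diet_ids)) % (2 ** 31)
    idx = 0
    for i, (diet, frac) in enumerate(zip(diet_ids, fractions)):
        glucose_params = {
            "intestinal": KineticParams(
                amplitude=(frac * glucose_fast.amplitude
                           + (1 - frac) * glucose_slow.amplitude),
                rate=frac * glucose_fast.rate + (1 - frac) * glucose_slow.rate,
                lag=frac * glucose_fast.lag + (1 - frac) * glucose_slow.lag,
            ),
        }
        nutrient_params = {
            "glucose": glucose_params,
            "soluble_nitrogen": per_diet(nitrogen, i),
            "total_amino_acids": per_diet(aa, i),
        }
        for nutrient, params in nutrient_params.items():
            noisy = {ph: _with_noise(p, noise_frac) for ph, p in params.items()}
            curves.extend(simulate_release_curve(
                noisy, PANEL_SCHEDULES[nutrient], diet, nutrient,
                PANEL_UNITS[nutrient], n_replicates=n_replicates,
                seed=int(sub_seeds[idx]),
            ))
            idx += 1
    return curves


def panel_rates_for_rel_gaa(targets: Sequence[float], *,
                            glucose_scale: float = 2.0,
                            nitrogen_scale: float = 0.135,
                            aa_scale: float = 3.5
                            ) -> list[dict[str, float]]:
    """Per-diet window rates realizing given Relative G/AA targets.

    The relative indices are constrained: the across-diet mean of each
    normalized rate is exactly 1, so the targets cannot be realized with
    identical nitrogen/amino-acid rates unless they average 1.  Writing
    the amino-acid weights as a convex mix a_d = (1 - t) + t / r_d makes
    the compatibility condition mean(r * a) = mean(a) linear in t, which
    this solves in closed form; glucose rates follow as g_d ∝ r_d * a_d.
    Nitrogen rates reuse the same construction, so Relative G/N equals
    Relative G/AA by design.  The ``*_scale`` arguments set the panel
    mean of each rate (units per minute).
    """
    r = np.asarray(targets, dtype=float)
    if np.any(r <= 0):
        raise SimulationError("Relative G/AA targets must be positive")
    if np.allclose(r, 1.0):
        a = np.ones_like(r)
    else:
        num = r.mean() - 1.0
        den = (r.mean() - 1.0) + ((1.0 / r).mean() - 1.0)
        if den == 0:
            raise SimulationError("degenerate target vector")
        t = num / den
        a = (1.0 - t) + t / r
        if np.any(a <= 0):
            raise SimulationError("target spread too wide for positive rates")
    g = r * a
    g = g / g.mean() * glucose_scale
    a_norm = a / a.mean()
    rates = []
    for gd, ad in zip(g, a_norm):
        rates.append({
            "glucose": gd,
            "soluble_nitrogen": ad * nitrogen_scale,
            "total_amino_acids": ad * aa_scale,
        })
    return rates


def amplitude_for_window_rate(k_window: float, rate_constant: float,
                              window: tuple[float, float] = (0.0, 20.0)
                              ) -> float:
    """Amplitude giving a first-order curve the requested window rate."""
    t1, t2 = window
    released = -math.expm1(-rate_constant * t2) - -math.expm1(-rate_constant * t1)
    if released <= 0:
        raise SimulationError("rate constant too small for the window")
    return k_window * (t2 - t1) / released


def simulate_targeted_panel(targets: Sequence[float],
                            diet_ids: Sequence[str] = DIET_IDS, *,
                            rate_constant: float = 0.04,
                            glucose_rate_constant: float = 0.03,
                            noise_frac: float = 0.0,
                            n_replicates: int = 3,
                            seed: int = 0) -> list[ReleaseCurve]:
    """Panel whose noiseless diet-level Relative G/AA equals ``targets``.

    Used for end-to-end recovery checks: the designed class labels are
    known, so the full curves -> rates -> indices -> classification
    pipeline can be scored against ground truth under replicate noise.
    """
    if len(targets) != len(diet_ids):
        raise SimulationError("need one target per diet id")
    window_rates = panel_rates_for_rel_gaa(targets)
    nitrogen_specs = []
    aa_specs = []
    glucose_amps = []
    for rates in window_rates:
        glucose_amps.append(amplitude_for_window_rate(
            rates["glucose"], glucose_rate_constant))
        nitrogen_specs.append({
            "gastric": KineticParams(amplitude=4.0, rate=0.02),
            "intestinal": KineticParams(
                amplitude=amplitude_for_window_rate(
                    rates["soluble_nitrogen"], rate_constant),
                rate=rate_constant),
        })
        aa_specs.append({
            "gastric": KineticParams(amplitude=15.0, rate=0.02),
            "intestinal": KineticParams(
                amplitude=amplitude_for_window_rate(
                    rates["total_amino_acids"], rate_constant),
                rate=rate_constant),
        })
    # express the glucose amplitudes through the fast/slow interpolation
    # machinery by passing per-diet "fractions" against bespoke endpoints
    amp = np.asarray(glucose_amps)
    fast = KineticParams(amplitude=float(amp.max()), rate=glucose_rate_constant)
    slow = KineticParams(amplitude=float(amp.min()), rate=glucose_rate_constant)
    if amp.max() == amp.min():
        fracs = np.ones_like(amp)
    else:
        fracs = (amp - amp.min()) / (amp.max() - amp.min())
    return simulate_diet_panel(
        fracs.tolist(), glucose_fast=fast, glucose_slow=slow,
        nitrogen=nitrogen_specs, aa=aa_specs, diet_ids=diet_ids,
        n_replicates=n_replicates, noise_frac=noise_frac, seed=seed,
    )


# ---------------------------------------------------------------------------
# Ingredient archetypes
# ---------------------------------------------------------------------------

#: Archetype axes -> kinetic regions (ingredient units, g/100 g sample).
_RATE_MAP = {"rapid": (0.030, 0.0), "slow": (0.006, 10.0)}  # (k base, lag)
_LEVEL_MAP = {"high": 80.0, "low": 30.0}                    # amplitude
_DURATION_MAP = {"persistent": 0.35, "transient": 1.6}      # k multiplier


def simulate_ingredient_panel(archetypes: Sequence[tuple[str, str, str]], *,
                              n_replicates: int = 3, sigma: float = 1.0,
                              seed: int = 0) -> list[ReleaseCurve]:
    """Ingredient-level glucose curves spanning the archetype grid.

    Each archetype is a (rate, level, duration) triple drawn from
    {rapid, slow} x {high, low} x {persistent, transient}; the three
    axes set the rate constant and lag, the amplitude, and how quickly
    the curve plateaus, respectively.  Units are g glucose per 100 g
    sample, intestinal phase only.
    """
    if not archetypes:
        raise SimulationError("need at least one archetype")
    curves = []
    sub_seeds = np.random.SeedSequence(seed).generate_state(
        len(archetypes)) % (2 ** 31)
    for i, (rate_tok, level_tok, duration_tok) in enumerate(archetypes):
        try:
            k_base, lag = _RATE_MAP[rate_tok]
            amplitude = _LEVEL_MAP[level_tok]
            k_mult = _DURATION_MAP[duration_tok]
        except KeyError as exc:
            raise SimulationError(f"unknown archetype token {exc.args[0]!r}") from None
        params = {"intestinal": KineticParams(
            amplitude=amplitude, rate=k_base * k_mult, lag=lag, sigma=sigma)}
        name = f"{rate_tok}_{level_tok}_{duration_tok}_{i + 1}"
        curves.extend(simulate_release_curve(
            params, {"intestinal": INTESTINAL_SCHEDULE}, name, "glucose",
            "g/100g", n_replicates=n_replicates, seed=int(sub_seeds[i]),
        ))
    return curves


# ---------------------------------------------------------------------------
# Virtual cannulated-pig trial
# ---------------------------------------------------------------------------

AMINO_ACIDS = ("lys", "met", "thr", "trp", "ile", "leu", "val", "phe")

#: Dietary amino-acid concentrations, g/kg DM (casein-dominated mix).
DEFAULT_AA_DIET = {
    "lys": 7.8, "met": 2.9, "thr": 4.2, "trp": 1.2,
    "ile": 4.9, "leu": 9.2, "val": 6.2, "phe": 4.8,
}

#: Basal ileal endogenous losses, g/kg dry-matter intake.
DEFAULT_IAA = {
    "lys": 0.40, "met": 0.11, "thr": 0.61, "trp": 0.14,
    "ile": 0.31, "leu": 0.52, "val": 0.46, "phe": 0.30,
}

#: Per-diet base AID (%), highest for the well-synchronized diets and
#: lowest where slow starch digestion keeps starch and protein
#: interacting; per-amino-acid offsets ride on top.
DEFAULT_BASE_AID = {
    "RGR_HGR": 84.0, "MRGR_MHGR": 86.0, "MGR_MGR": 76.0,
    "MSGR_MLGR": 80.0, "SGR_LGR": 82.0,
}
DEFAULT_AID_OFFSET = {
    "lys": 2.0, "met": 4.0, "thr": -3.0, "trp": -2.0,
    "ile": 1.0, "leu": 2.5, "val": 0.0, "phe": 1.5,
}

#: Per-diet whole-animal truths for the balance side of the trial.
DEFAULT_ATTD_GE = {"RGR_HGR": 60.1, "MRGR_MHGR": 66.4, "MGR_MGR": 56.8,
                   "MSGR_MLGR": 55.3, "SGR_LGR": 56.4}
DEFAULT_FECAL_N_FRAC = {"RGR_HGR": 71.2, "MRGR_MHGR": 58.5, "MGR_MGR": 79.2,
                        "MSGR_MLGR": 86.5, "SGR_LGR": 65.9}
DEFAULT_URINE_N_FRAC = {"RGR_HGR": 13.8, "MRGR_MHGR": 15.1, "MGR_MGR": 15.2,
                        "MSGR_MLGR": 12.3, "SGR_LGR": 9.32}
DEFAULT_URINE_GE_FRAC = {"RGR_HGR": 1.82, "MRGR_MHGR": 1.95, "MGR_MGR": 1.81,
                         "MSGR_MLGR": 2.32, "SGR_LGR": 1.37}
DEFAULT_ADG = {"RGR_HGR": 0.56, "MRGR_MHGR": 0.61, "MGR_MGR": 0.48,
               "MSGR_MLGR": 0.49, "SGR_LGR": 0.44}
DEFAULT_ADFI = {"RGR_HGR": 1.26, "MRGR_MHGR": 1.22, "MGR_MGR": 1.25,
                "MSGR_MLGR": 1.24, "SGR_LGR": 1.28}

#: Elemental chromium fraction of Cr2O3 (2 * 52.00 / 151.99).
CR_FRACTION_OF_CR2O3 = 0.684


@dataclass
class TrialConfig:
    """Configuration and ground truth for the virtual trial.

    The defaults emulate the study conditions: six ileal-cannulated pigs
    per diet over a 9-day period, a nitrogen-free diet fed only to
    estimate endogenous losses, 0.3% Cr2O3 in every diet, and group-level
    digestibility/growth truths on the scale reported for this kind of
    trial.  ``assay_cv`` is the relative s.d. of each chemical assay;
    ``noise`` scales every noise source at once (0 gives an exactly
    invertible dataset).
    """

    diet_ids: tuple[str, ...] = DIET_IDS
    nf_diet_id: str = "NF"
    n_per_diet: int = 6
    true_aid: dict[str, dict[str, float]] = field(default_factory=lambda: {
        diet: {aa: DEFAULT_BASE_AID[diet] + DEFAULT_AID_OFFSET[aa]
               for aa in AMINO_ACIDS}
        for diet in DIET_IDS
    })
    true_iaa: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IAA))
    aa_diet: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_DIET))
    crude_protein_diet: float = 95.0            # g/kg DM
    cr_diet: float = 3.0 * CR_FRACTION_OF_CR2O3  # g Cr/kg DM from 0.3% Cr2O3
    cr_digesta_base: float = 6.0                 # g Cr/kg digesta DM
    ge_diet: float = 17.8                        # MJ/kg
    n_diet: float = 15.2                         # g N/kg feed
    true_attd_ge: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTD_GE))
    fecal_n_frac: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FECAL_N_FRAC))
    urine_n_frac: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_URINE_N_FRAC))
    urine_ge_frac: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_URINE_GE_FRAC))
    true_adg: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_ADG))
    true_adfi: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ADFI))
    bw_start_mean: float = 28.88                 # kg
    bw_start_sd: float = 3.06
    days: float = 9.0
    assay_cv: float = 0.04
    feed_sd: float = 0.06                        # kg/d
    adg_sd: float = 0.09                         # kg/d between animals
    noise: float = 1.0

    def validate(self) -> None:
        if self.n_per_diet < 2:
            raise SimulationError("need at least two animals per diet")
        for diet, per_aa in self.true_aid.items():
            for aa, value in per_aa.items():
                if not 0.0 <= value <= 100.0:
                    raise SimulationError(
                        f"true AID for {diet}/{aa} is {value}; must lie in "
                        "[0, 100]"
                    )
        for name in ("true_attd_ge", "fecal_n_frac", "urine_n_frac",
                     "urine_ge_frac"):
            for diet, value in getattr(self, name).items():
                if not 0.0 <= value <= 100.0:
                    raise SimulationError(f"{name}[{diet}] out of [0, 100]")


@dataclass
class TrialData:
    """Simulated trial tables plus the ground truth that generated them."""

    diet_assays: dict[str, DietAssay]
    digesta_assays: list[DigestaAssay]
    balance_records: list[BalanceRecord]
    truth: pd.DataFrame


def simulate_trial(config: TrialConfig | None = None, *,
                   seed: int = 0) -> TrialData:
    """Generate diet assays, digesta assays and balance records.

    Digesta concentrations are produced by inverting the marker-ratio
    digestibility equations at the configured truths, so with
    ``config.noise = 0`` the analysis pipeline recovers every truth
    exactly; with noise on, multiplicative assay errors (mean 1) perturb
    each measured concentration independently.
    """
    config = config or TrialConfig()
    config.validate()
    scale = config.noise
    rng_assay, rng_balance, rng_animal = _spawn_rngs(seed, 3)

    def jitter(rng, cv):
        return 1.0 + scale * cv * rng.standard_normal()

    diet_assays: dict[str, DietAssay] = {}
    for diet in config.diet_ids:
        diet_assays[diet] = DietAssay(
            diet_id=diet, amino_acids=dict(config.aa_diet),
            crude_protein=config.crude_protein_diet,
            chromium=config.cr_diet, gross_energy=config.ge_diet,
        )
    diet_assays[config.nf_diet_id] = DietAssay(
        diet_id=config.nf_diet_id, amino_acids={aa: 0.0 for aa in config.aa_diet},
        crude_protein=0.0, chromium=config.cr_diet,
        gross_energy=config.ge_diet,
    )

    digesta: list[DigestaAssay] = []
    balance: list[BalanceRecord] = []
    animal_no = 0
    for diet in (*config.diet_ids, config.nf_diet_id):
        for _ in range(config.n_per_diet):
            animal_no += 1
            animal_id = f"pig{animal_no:03d}"
            cr_true = config.cr_digesta_base
            if diet == config.nf_diet_id:
                aa_true = {
                    aa: config.true_iaa.get(aa, 0.0) * cr_true / config.cr_diet
                    for aa in config.aa_diet
                }
                cp_true = 0.0
            else:
                aa_true = {
                    aa: (config.aa_diet[aa]
                         * (1.0 - config.true_aid[diet][aa] / 100.0)
                         * cr_true / config.cr_diet)
                    for aa in config.aa_diet
                }
                mean_aid = float(np.mean(list(config.true_aid[diet].values())))
                cp_true = (config.crude_protein_diet * (1.0 - mean_aid / 100.0)
                           * cr_true / config.cr_diet)
            digesta.append(DigestaAssay(
                animal_id=animal_id, diet_id=diet,
                amino_acids={aa: v * jitter(rng_assay, config.assay_cv)
                             for aa, v in aa_true.items()},
                chromium=cr_true * jitter(rng_assay, config.assay_cv),
                crude_protein=cp_true * jitter(rng_assay, config.assay_cv),
            ))

            if diet == config.nf_diet_id:
                continue  # NF animals contribute no balance comparison rows
            feed = config.true_adfi[diet] + scale * config.feed_sd \
                * rng_balance.standard_normal()
            feed = max(feed, 0.5)
            intake_n = feed * config.n_diet
            intake_ge = feed * config.ge_diet
            fecal_ge = intake_ge * (1.0 - config.true_attd_ge[diet] / 100.0) \
                * jitter(rng_balance, config.assay_cv)
            fecal_n = intake_n * config.fecal_n_frac[diet] / 100.0 \
                * jitter(rng_balance, config.assay_cv)
            urine_n = intake_n * config.urine_n_frac[diet] / 100.0 \
                * jitter(rng_balance, config.assay_cv)
            urine_ge = intake_ge * config.urine_ge_frac[diet] / 100.0 \
                * jitter(rng_balance, config.assay_cv)
            bw_start = config.bw_start_mean + scale * config.bw_start_sd \
                * rng_animal.standard_normal()
            adg = config.true_adg[diet] + scale * config.adg_sd \
                * rng_animal.standard_normal()
            balance.append(BalanceRecord(
                animal_id=animal_id, diet_id=diet,
                intake_n=intake_n, fecal_n=max(fecal_n, 0.0),
                urine_n=max(urine_n, 0.0), intake_ge=intake_ge,
                fecal_ge=max(fecal_ge, 0.0), urine_ge=max(urine_ge, 0.0),
                bw_start=bw_start, bw_end=bw_start + adg * config.days,
                days=config.days, feed_total=feed * config.days,
            ))

    truth_rows = []
    for diet in config.diet_ids:
        for aa in config.aa_diet:
            truth_rows.append({
                "diet_id": diet, "quantity": "aid", "analyte": aa,
                "value": config.true_aid[diet][aa],
            })
            truth_rows.append({
                "diet_id": diet, "quantity": "sid", "analyte": aa,
                "value": config.true_aid[diet][aa]
                + config.true_iaa.get(aa, 0.0) / config.aa_diet[aa] * 100.0,
            })
        truth_rows.append({"diet_id": diet, "quantity": "attd_ge",
                           "analyte": "", "value": config.true_attd_ge[diet]})
        truth_rows.append({"diet_id": diet, "quantity": "attd_n", "analyte": "",
                           "value": 100.0 - config.fecal_n_frac[diet]})
        truth_rows.append({"diet_id": diet, "quantity": "adg", "analyte": "",
                           "value": config.true_adg[diet]})
    for aa, value in config.true_iaa.items():
        truth_rows.append({"diet_id": config.nf_diet_id, "quantity": "iaa",
                           "analyte": aa, "value": value})
    return TrialData(
        diet_assays=diet_assays,
        digesta_assays=digesta,
        balance_records=balance,
        truth=pd.DataFrame(truth_rows),
    )
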