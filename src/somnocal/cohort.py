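"""Synthetic study cohort: subjects, hypnograms, and ground-truth energy
expenditure with the statistical structure the analysis assumes.

The default configuration emulates a five-group design — male runners,
amenorrheic runners, menstruating runners, female controls and male
controls (n = 9/8/9/10/10) — with group body composition, sleep-stage
durations and measured/estimated rate levels matching the published
group summaries.  Menstruating subjects can be simulated in a paired
follicular/luteal design in which the luteal night's EE is elevated by a
configurable multiplier (default 1.027, i.e. +2.7%).

Stage-dependent EE is modelled as a subject basal level times a stage
multiplier (slow-wave sleep lowest), a slow within-night drift, and
multiplicative log-normal noise at two scales: minute-to-minute and
night-to-night.  The generator can invert its own EE through the Weir
equation to produce ground-truth gas-exchange series, closing the loop
for end-to-end pipeline tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .calorimetry import (
    EESeries,
    KCAL_TO_KJ,
    MINUTES_PER_DAY,
    RMR_SEGMENT_MIN,
    SLEEP_SEGMENT_MIN,
    WeirCoefficients,
)
from .chamber import GasExchangeSeries
from .hypnogram import EPOCH_SECONDS, Hypnogram
from .reference import estimate_smr

__all__ = [
    "SubjectProfile",
    "TissueMasses",
    "GroupSpec",
    "CohortConfig",
    "DEFAULT_GROUPS",
    "generate_cohort",
    "composition_variant",
    "simulate_hypnogram",
    "simulate_true_ee",
    "simulate_supine_rmr",
    "gas_from_ee",
]

EPOCHS_PER_NIGHT = int(SLEEP_SEGMENT_MIN * 60 / EPOCH_SECONDS)  # 960

#: FFM partition used to synthesize tissue masses (fraction of FFM);
#: adipose tissue is set to FM, residual takes the remainder.
TISSUE_FRACTIONS = {"brain": 0.02, "skeletal_muscle": 0.50, "bone": 0.07}


@dataclass
class TissueMasses:
    """Organ/tissue masses (kg) feeding the tissue-based RMR estimate."""

    brain: float
    skeletal_muscle: float
    bone: float
    adipose: float
    residual: float

    def __post_init__(self) -> None:
        for name in ("brain", "skeletal_muscle", "bone", "adipose", "residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name} mass")

    @property
    def total(self) -> float:
        return self.brain + self.skeletal_muscle + self.bone + self.adipose + self.residual


@dataclass
class SubjectProfile:
    """One simulated participant.

    ``sex_code`` uses the estimation-equation convention (1 = male,
    2 = female).  ``true_smr_kj_day`` / ``true_rmr_kj_day`` are the
    generator's latent metabolic levels — the quantities the measurement
    pipeline is supposed to recover, never inputs to it.
    """

    subject_id: str
    sex_code: int
    group: str
    menstrual_status: str  # amenorrhea | menstruating | not_applicable
    phase: str             # follicular | luteal | none
    body_mass_kg: float
    height_cm: float
    ffm_kg: float
    fm_kg: float
    urinary_nitrogen_g_day: float
    energy_intake_kcal_day: float
    exercise_ee_kcal_day: float
    active_ee_kcal_day: float
    habitual_bedtime: str = "23:00"
    tissues: TissueMasses | None = None
    true_smr_kj_day: float = 0.0
    true_rmr_kj_day: float = 0.0

    def __post_init__(self) -> None:
        if self.sex_code not in (1, 2):
            raise ValueError("sex_code must be 1 or 2")
        if self.ffm_kg <= 0 or self.fm_kg < 0:
            raise ValueError("FFM must be positive and FM nonnegative")
        if self.sex_code == 1 and self.menstrual_status != "not_applicable":
            raise ValueError("male subjects must have menstrual_status 'not_applicable'")

    @property
    def basal_kj_min(self) -> float:
        return self.true_smr_kj_day / MINUTES_PER_DAY


@dataclass(frozen=True)
class GroupSpec:
    """Targets for one study group.

    Body-composition and sleep-architecture targets are group means (SDs
    where the generator draws per subject); ``smr_ratio`` scales the
    latent SMR relative to its FFM-based estimate, and ``pal`` / ``ea``
    set the activity and energy-availability levels.
    """

    label: str
    n: int
    sex_code: int
    menstrual_status: str
    ffm_mean: float
    ffm_sd: float
    fm_mean: float
    fm_sd: float
    height_mean: float
    height_sd: float
    stage_minutes: dict          # N1/N2/N3/R target minutes per night
    waso_min: float
    spt_min: float
    smr_ratio: float
    pal: float
    ea_kcal_kg_ffm: float
    exercise_ee_kcal: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r}: size must be >= 1")
        for nm in ("ffm_sd", "fm_sd", "height_sd"):
            if getattr(self, nm) < 0:
                raise ValueError(f"group {self.label!r}: {nm} must be >= 0")

    @property
    def tst_min(self) -> float:
        return float(sum(self.stage_minutes.values()))


def _grp(**kw) -> GroupSpec:
    return GroupSpec(**kw)


#: Default five-group design; targets are published group means.
DEFAULT_GROUPS: dict[str, GroupSpec] = {
    "male_runner": _grp(
        label="male_runner", n=9, sex_code=1, menstrual_status="not_applicable",
        ffm_mean=55.3, ffm_sd=5.6, fm_mean=4.8, fm_sd=1.1,
        height_mean=173.3, height_sd=8.0,
        stage_minutes={"N1": 38.0, "N2": 237.6, "N3": 93.5, "R": 96.8},
        waso_min=10.3, spt_min=476.2, smr_ratio=1.10,
        pal=2.12, ea_kcal_kg_ffm=24.5, exercise_ee_kcal=800.0,
    ),
    "amenorrheic_runner": _grp(
        label="amenorrheic_runner", n=8, sex_code=2, menstrual_status="amenorrhea",
        ffm_mean=38.2, ffm_sd=3.3, fm_mean=8.5, fm_sd=3.5,
        height_mean=156.5, height_sd=5.3,
        stage_minutes={"N1": 34.8, "N2": 233.7, "N3": 104.6, "R": 83.3},
        waso_min=16.6, spt_min=473.0, smr_ratio=0.99,
        pal=2.07, ea_kcal_kg_ffm=37.0, exercise_ee_kcal=800.0,
    ),
    "menstruating_runner": _grp(
        label="menstruating_runner", n=9, sex_code=2, menstrual_status="menstruating",
        ffm_mean=39.6, ffm_sd=2.8, fm_mean=9.1, fm_sd=2.1,
        height_mean=160.9, height_sd=4.6,
        stage_minutes={"N1": 24.3, "N2": 256.6, "N3": 94.3, "R": 79.6},
        waso_min=16.4, spt_min=471.2, smr_ratio=0.94,
        pal=1.97, ea_kcal_kg_ffm=36.2, exercise_ee_kcal=800.0,
    ),
    "female_control": _grp(
        label="female_control", n=10, sex_code=2, menstrual_status="menstruating",
        ffm_mean=39.3, ffm_sd=4.5, fm_mean=15.1, fm_sd=5.3,
        height_mean=162.3, height_sd=7.2,
        stage_minutes={"N1": 37.8, "N2": 232.1, "N3": 97.1, "R": 84.5},
        waso_min=19.0, spt_min=470.5, smr_ratio=0.93,
        pal=1.70, ea_kcal_kg_ffm=43.6, exercise_ee_kcal=150.0,
    ),
    "male_control": _grp(
        label="male_control", n=10, sex_code=1, menstrual_status="not_applicable",
        ffm_mean=54.7, ffm_sd=5.2, fm_mean=10.6, fm_sd=4.4,
        height_mean=175.3, height_sd=4.5,
        stage_minutes={"N1": 52.4, "N2": 238.6, "N3": 80.9, "R": 82.5},
        waso_min=17.6, spt_min=471.9, smr_ratio=1.05,
        pal=1.65, ea_kcal_kg_ffm=36.3, exercise_ee_kcal=150.0,
    ),
}

#: Stage multipliers on the basal sleeping level.  Slow-wave sleep (N3)
#: carries the lowest EE; wake the highest.
DEFAULT_STAGE_MULTIPLIERS = {"W": 1.15, "N1": 1.05, "N2": 1.00, "N3": 0.95, "R": 1.08}


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    ``luteal_smr_multiplier`` scales every luteal-night EE minute of a
    menstruating subject (default 1.027, a 2.7% elevation).
    ``ee_noise_cv`` is the minute-to-minute coefficient of variation of
    the multiplicative log-normal EE noise; ``night_cv`` an additional
    night-level factor capturing day-to-day biological variation (set
    near the reported repeatability of sleeping metabolic rate).
    """

    groups: dict = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    luteal_smr_multiplier: float = 1.027
    stage_multipliers: dict = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MULTIPLIERS))
    ee_noise_cv: float = 0.05
    night_cv: float = 0.033
    drift_amplitude: float = 0.04
    wake_probability: float = 1.0
    between_subject_cv: float = 0.06
    rmr_to_smr: float = 1.11
    stage_total_cv: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.luteal_smr_multiplier <= 0:
            raise ValueError("luteal_smr_multiplier must be positive")
        if any(m <= 0 for m in self.stage_multipliers.values()):
            raise ValueError("stage multipliers must be positive")
        for nm in ("ee_noise_cv", "night_cv", "drift_amplitude",
                   "wake_probability", "between_subject_cv", "stage_total_cv"):
            if getattr(self, nm) < 0:
                raise ValueError(f"{nm} must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative log-normal factor(s) with mean exactly 1."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


_GROUP_PREFIX = {
    "male_runner": "MR", "amenorrheic_runner": "AR", "menstruating_runner": "FR",
    "female_control": "FC", "male_control": "MC",
}


def generate_cohort(config: CohortConfig | None = None) -> list[SubjectProfile]:
    """Draw the full cohort (deterministic in ``config.seed``).

    FFM and FM are drawn independently per subject around the group
    targets; body mass closes as their sum.  Tissue masses partition FFM
    by fixed fractions (brain 2%, skeletal muscle 50%, bone 7%, residual
    the remainder) with adipose tissue equal to FM.  The latent sleeping
    metabolic rate is the group's measured/estimated ratio times the
    FFM-based SMR estimate, times a between-subject log-normal factor;
    the latent RMR is a fixed multiple of it.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    subjects: list[SubjectProfile] = []
    for label, g in config.groups.items():
        prefix = _GROUP_PREFIX.get(label, label[:2].upper())
        for i in range(g.n):
            ffm = max(20.0, rng.normal(g.ffm_mean, g.ffm_sd))
            fm = max(0.5, rng.normal(g.fm_mean, g.fm_sd))
            height = rng.normal(g.height_mean, g.height_sd)
            tissues = TissueMasses(
                brain=TISSUE_FRACTIONS["brain"] * ffm,
                skeletal_muscle=TISSUE_FRACTIONS["skeletal_muscle"] * ffm,
                bone=TISSUE_FRACTIONS["bone"] * ffm,
                adipose=fm,
                residual=(1.0 - sum(TISSUE_FRACTIONS.values())) * ffm,
            )
            true_smr = (g.smr_ratio * estimate_smr(ffm)
                        * _lognormal_factor(rng, config.between_subject_cv))
            true_rmr = config.rmr_to_smr * true_smr
            active_kcal = max(
                0.0,
                (g.pal - 1.0) * true_rmr / KCAL_TO_KJ
                * _lognormal_factor(rng, 0.08),
            )
            exercise = max(0.0, rng.normal(g.exercise_ee_kcal, 0.15 * g.exercise_ee_kcal))
            intake = g.ea_kcal_kg_ffm * ffm + exercise
            phase = "follicular" if g.menstrual_status == "menstruating" else "none"
            subjects.append(SubjectProfile(
                subject_id=f"{prefix}{i + 1:02d}",
                sex_code=g.sex_code,
                group=label,
                menstrual_status=g.menstrual_status,
                phase=phase,
                body_mass_kg=ffm + fm,
                height_cm=height,
                ffm_kg=ffm,
                fm_kg=fm,
                urinary_nitrogen_g_day=max(4.0, rng.normal(11.0, 2.0)),
                energy_intake_kcal_day=intake,
                exercise_ee_kcal_day=exercise,
                active_ee_kcal_day=active_kcal,
                tissues=tissues,
                true_smr_kj_day=true_smr,
                true_rmr_kj_day=true_rmr,
            ))
    return subjects


# fraction of each stage's nightly total allotted to ultradian cycles 1-5:
# N3 front-loaded (deep sleep dominates early cycles), REM back-loaded.
_CYCLE_WEIGHTS = {
    "N3": np.array([0.35, 0.27, 0.18, 0.12, 0.08]),
    "R": np.array([0.06, 0.14, 0.20, 0.27, 0.33]),
    "N1": np.full(5, 0.2),
    "N2": np.full(5, 0.2),
    "W": np.array([0.10, 0.20, 0.20, 0.25, 0.25]),
}


def simulate_hypnogram(
    subject: SubjectProfile,
    seed: int | None,
    config: CohortConfig | None = None,
) -> Hypnogram:
    """One night of 960 30-s epochs for ``subject``'s group.

    A semi-Markov construction: nightly stage totals are drawn around
    the group targets, split across five ~95-min ultradian cycles with
    N3 concentrated early and REM late, and each cycle laid out as
    N1 - N2 - N3 - N2 - wake - REM.  Sleep-onset latency fills the gap
    between the sleep-period-time target and the 8-h opportunity;
    trailing wake pads the night to exactly 960 epochs.
    ``config.wake_probability`` scales interior wake (0 gives a night
    with no wake after sleep onset).
    """
    if seed is None:
        raise ValueError("simulate_hypnogram requires an explicit seed")
    config = config or CohortConfig()
    g = config.groups[subject.group]
    rng = np.random.default_rng(seed)

    latency = max(0.0, rng.normal(SLEEP_SEGMENT_MIN - g.spt_min, 1.5))
    totals = {
        s: max(1.0, rng.normal(t, config.stage_total_cv * t))
        for s, t in g.stage_minutes.items()
    }
    totals["W"] = config.wake_probability * max(0.0, rng.normal(g.waso_min, 0.5 * g.waso_min))
    # shrink an over-long schedule proportionally rather than truncating the
    # REM-rich final cycle at the 8-h boundary
    available = SLEEP_SEGMENT_MIN - latency
    scheduled = sum(totals.values())
    if scheduled > available:
        totals = {s: v * available / scheduled for s, v in totals.items()}

    chunks: list[np.ndarray] = [np.repeat("W", int(round(latency * 2)))]
    n_cycles = len(_CYCLE_WEIGHTS["N3"])
    # jitter the cycle allocation, preserving each stage's nightly total
    weights = {}
    for s, w in _CYCLE_WEIGHTS.items():
        jw = w * _lognormal_factor(rng, 0.15, len(w))
        weights[s] = jw / jw.sum()
    for c in range(n_cycles):
        minutes = {s: totals[s] * weights[s][c] for s in totals}
        order = ["N1", "N2", "N3", "N2", "W", "R"]
        shares = {"N2": 0.5}
        for stage in order:
            mins = minutes[stage] * shares.get(stage, 1.0)
            n_ep = int(round(mins * 2))
            if n_ep > 0:
                chunks.append(np.repeat(stage, n_ep))
    epochs = np.concatenate(chunks)
    if len(epochs) < EPOCHS_PER_NIGHT:
        epochs = np.concatenate(
            [epochs, np.repeat("W", EPOCHS_PER_NIGHT - len(epochs))])
    return Hypnogram(epochs[:EPOCHS_PER_NIGHT], lights_off=subject.habitual_bedtime)


def _minute_multipliers(h: Hypnogram, stage_multipliers: dict) -> np.ndarray:
    """Per-minute stage multiplier; split minutes average their two epochs."""
    mult = np.array([stage_multipliers[s] for s in h.epochs])
    n_min = len(mult) // 2
    return mult[: n_min * 2].reshape(n_min, 2).mean(axis=1)


def simulate_true_ee(
    subject: SubjectProfile,
    hypnogram: Hypnogram,
    config: CohortConfig | None = None,
    seed: int | None = None,
    phase: str | None = None,
) -> EESeries:
    """Ground-truth minute EE over the 8-h sleep period.

    EE(t) = basal * stage multiplier * drift(t) * night factor * minute
    noise, where drift is a slow sinusoidal dip reaching its minimum
    mid-night (amplitude ``config.drift_amplitude``), and the luteal
    multiplier applies when the (possibly overridden) phase is luteal.
    """
    if seed is None:
        raise ValueError("simulate_true_ee requires an explicit seed")
    config = config or CohortConfig()
    if hypnogram.duration_min != SLEEP_SEGMENT_MIN:
        raise ValueError("hypnogram must cover the 8-h sleep window")
    rng = np.random.default_rng(seed)
    n = int(hypnogram.duration_min)
    mult = _minute_multipliers(hypnogram, config.stage_multipliers)
    t = np.arange(n)
    drift = 1.0 - config.drift_amplitude * np.sin(np.pi * t / n)
    phase = subject.phase if phase is None else phase
    phase_factor = config.luteal_smr_multiplier if phase == "luteal" else 1.0
    night = _lognormal_factor(rng, config.night_cv)
    noise = _lognormal_factor(rng, config.ee_noise_cv, n)
    ee = subject.basal_kj_min * mult * drift * phase_factor * night * noise
    return EESeries(ee, segments={"sleep": (0, n)})


def simulate_supine_rmr(
    subject: SubjectProfile,
    config: CohortConfig | None = None,
    seed: int | None = None,
) -> EESeries:
    """A 30-min supine resting measurement at the subject's latent RMR
    with minute-level noise (same CV as the night series)."""
    if seed is None:
        raise ValueError("simulate_supine_rmr requires an explicit seed")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    level = subject.true_rmr_kj_day / MINUTES_PER_DAY
    ee = level * _lognormal_factor(rng, config.ee_noise_cv, RMR_SEGMENT_MIN)
    return EESeries(np.asarray(ee), segments={"supine_rmr": (0, RMR_SEGMENT_MIN)})


def composition_variant(
    subject: SubjectProfile,
    ffm_offset_kg: float = 0.0,
    fm_offset_kg: float = 0.0,
) -> SubjectProfile:
    """A copy of ``subject`` with shifted FFM/FM and re-partitioned
    tissue masses.

    Emulates a second body-composition measurement method (e.g.
    absorptiometry vs impedance) whose systematic offset propagates into
    the estimation equations; the latent metabolic levels are unchanged.
    """
    ffm = subject.ffm_kg + ffm_offset_kg
    fm = subject.fm_kg + fm_offset_kg
    if ffm <= 0 or fm < 0:
        raise ValueError("offsets produce non-physiologic composition")
    tissues = TissueMasses(
        brain=TISSUE_FRACTIONS["brain"] * ffm,
        skeletal_muscle=TISSUE_FRACTIONS["skeletal_muscle"] * ffm,
        bone=TISSUE_FRACTIONS["bone"] * ffm,
        adipose=fm,
        residual=(1.0 - sum(TISSUE_FRACTIONS.values())) * ffm,
    )
    return replace(subject, ffm_kg=ffm, fm_kg=fm, body_mass_kg=ffm + fm,
                   tissues=tissues)


def gas_from_ee(
    ee: EESeries,
    rer_target: float,
    urinary_nitrogen_g_day: float = 0.0,
    coefficients: WeirCoefficients | None = None,
) -> GasExchangeSeries:
    """Invert the Weir equation: gas exchange that reproduces ``ee``.

    Every minute satisfies VCO2/VO2 = ``rer_target``; applying
    :func:`somnocal.calorimetry.weir_ee` to the output returns the input
    EE exactly (same coefficients and nitrogen).
    """
    if not 0.6 <= rer_target <= 1.3:
        raise ValueError(f"rer_target {rer_target} outside [0.6, 1.3]")
    if np.any(ee.ee_kj_min < 0):
        raise ValueError("EE must be nonnegative")
    c = coefficients or WeirCoefficients()
    un_per_min = urinary_nitrogen_g_day / MINUTES_PER_DAY
    ee_kcal = ee.ee_kj_min / KCAL_TO_KJ
    vo2 = (ee_kcal + c.nitrogen * un_per_min) / (c.o2 + c.co2 * rer_target)
    return GasExchangeSeries(vo2, rer_target * vo2,
                             urinary_nitrogen_g_day=urinary_nitrogen_g_day)
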