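"""End-to-end study pipeline over the synthetic cohort.

One subject-night travels: hypnogram -> ground-truth minute EE -> gas
exchange (Weir inversion) -> chamber forward simulation -> deconvolution
-> Weir EE -> sleep-period metrics (mSMR, mOMR, stage EE) -> reference
rates and ratios -> group statistics.  The chamber leg can run noise-free
(exact inversion) or with mass-spectrometer sensor noise and regularized
deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calorimetry, chamber, cohort, reference, sleep, stats

__all__ = ["NightResult", "StudyResult", "simulate_night", "paired_phase_msmr",
           "run_study"]


@dataclass
class NightResult:
    """Everything measured for one subject-night."""

    subject: cohort.SubjectProfile
    phase: str
    hypnogram: object
    true_ee: calorimetry.EESeries
    measured_ee: calorimetry.EESeries
    architecture: sleep.SleepArchitecture
    summary: sleep.MetabolicSummary
    qc: calorimetry.QCReport


@dataclass
class StudyResult:
    """Tables and test results of one full synthetic study run."""

    subjects: pd.DataFrame
    nights: list
    summaries: pd.DataFrame
    correlations: dict
    anova_msmr: stats.ComparisonResult
    ancova_msmr: stats.ComparisonResult
    timecourse: dict
    paired: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)


def _measure_night(
    subject: cohort.SubjectProfile,
    hypnogram,
    true_ee: calorimetry.EESeries,
    rer: float,
    sensor_noise: bool,
    spec: chamber.ChamberSpec,
    rng: np.random.Generator,
) -> calorimetry.EESeries:
    """Push a true EE series through chamber physics and back."""
    gas_true = cohort.gas_from_ee(true_ee, rer, subject.urinary_nitrogen_g_day)
    trace = chamber.forward_chamber(gas_true, spec, noise=sensor_noise, rng=rng)
    gas_rec = chamber.deconvolve(
        trace, urinary_nitrogen_g_day=subject.urinary_nitrogen_g_day)
    measured = calorimetry.weir_ee(gas_rec, segments={"sleep": (0, len(gas_rec))})
    return measured


def simulate_night(
    subject: cohort.SubjectProfile,
    config: cohort.CohortConfig,
    seed: int,
    phase: str | None = None,
    hypnogram=None,
    rer: float = 0.85,
    sensor_noise: bool = False,
    chamber_spec: chamber.ChamberSpec | None = None,
) -> NightResult:
    """Simulate and measure one night for one subject.

    ``sensor_noise=False`` keeps the chamber leg noise-free so the
    deconvolution is exact; with noise, the smoothness-regularized
    inversion is used.  Passing ``hypnogram`` reuses a night's sleep
    architecture (the paired-phase design keeps it fixed across phases).
    """
    ss = np.random.SeedSequence(seed)
    s_hyp, s_ee, s_noise = (np.random.default_rng(c) for c in ss.spawn(3))
    if hypnogram is None:
        hypnogram = cohort.simulate_hypnogram(
            subject, int(s_hyp.integers(2**31)), config)
    true_ee = cohort.simulate_true_ee(
        subject, hypnogram, config, int(s_ee.integers(2**31)), phase=phase)
    spec = chamber_spec or chamber.ChamberSpec(
        sensor_noise_sd=chamber.ChamberSpec().sensor_noise_sd if sensor_noise else 0.0)
    measured = _measure_night(subject, hypnogram, true_ee, rer,
                              sensor_noise, spec, s_noise)
    arch = sleep.score_architecture(hypnogram)
    summary = sleep.summarize_night(measured, hypnogram)
    qc = calorimetry.qc_exclude(hypnogram, measured)
    return NightResult(subject, phase or subject.phase, hypnogram, true_ee,
                       measured, arch, summary, qc)


def paired_phase_msmr(
    subjects,
    config: cohort.CohortConfig,
    seed: int,
    **night_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Follicular and luteal mSMR for each subject, full pipeline.

    Each subject keeps one hypnogram across both phases; EE noise is
    redrawn per night.  Returns ``(msmr_follicular, msmr_luteal)``.
    """
    ss = np.random.SeedSequence(seed)
    f_out, l_out = [], []
    for subject, child in zip(subjects, ss.spawn(len(subjects))):
        s_hyp, s_f, s_l = child.spawn(3)
        hyp = cohort.simulate_hypnogram(
            subject, int(np.random.default_rng(s_hyp).integers(2**31)), config)
        nf = simulate_night(subject, config,
                            int(np.random.default_rng(s_f).integers(2**31)),
                            phase="follicular", hypnogram=hyp, **night_kwargs)
        nl = simulate_night(subject, config,
                            int(np.random.default_rng(s_l).integers(2**31)),
                            phase="luteal", hypnogram=hyp, **night_kwargs)
        f_out.append(nf.summary.msmr_kj_day)
        l_out.append(nl.summary.msmr_kj_day)
    return np.asarray(f_out), np.asarray(l_out)


def run_study(
    config: cohort.CohortConfig | None = None,
    seed: int = 0,
    sensor_noise: bool = False,
) -> StudyResult:
    """Run the whole synthetic study once.

    Generates the five-group cohort, measures one night per subject
    (plus a paired luteal night for menstruating subjects and a supine
    RMR block for everyone), applies QC, and runs the statistical
    battery: rate correlations, five-group ANOVA and FFM/FM-adjusted
    ANCOVA on mSMR, the 16-bin time-course split-plot comparison of
    runners vs controls, paired phase tests, and the a-priori power
    computation.
    """
    config = config or cohort.CohortConfig(seed=seed)
    subjects = cohort.generate_cohort(config)
    ss = np.random.SeedSequence(seed + 1)
    nights: list[NightResult] = []
    luteal_pairs: dict[str, dict[str, float]] = {}
    rows = []
    for subject, child in zip(subjects, ss.spawn(len(subjects))):
        s_night, s_rmr, s_lut = child.spawn(3)
        night = simulate_night(
            subject, config, int(np.random.default_rng(s_night).integers(2**31)),
            sensor_noise=sensor_noise)
        supine = cohort.simulate_supine_rmr(
            subject, config, int(np.random.default_rng(s_rmr).integers(2**31)))
        mrmr = calorimetry.measure_rmr(supine)
        night.summary.mrmr_kj_day = mrmr
        nights.append(night)
        if subject.menstrual_status == "menstruating":
            lut = simulate_night(
                subject, config, int(np.random.default_rng(s_lut).integers(2**31)),
                phase="luteal", hypnogram=night.hypnogram,
                sensor_noise=sensor_noise)
            nights.append(lut)
            luteal_pairs[subject.subject_id] = {
                "follicular": night.summary.msmr_kj_day,
                "luteal": lut.summary.msmr_kj_day,
            }
        rates = reference.ReferenceRates(
            est_rmr_kj_day=reference.estimate_rmr(subject.tissues),
            est_smr_kj_day=reference.estimate_smr(subject.ffm_kg),
            est_omr_kj_day=reference.estimate_omr(
                subject.ffm_kg, subject.fm_kg, subject.sex_code),
        )
        reference.metabolic_ratios(night.summary, rates)
        total_ee = mrmr + subject.active_ee_kcal_day * calorimetry.KCAL_TO_KJ
        rows.append({
            "subject_id": subject.subject_id,
            "group": subject.group,
            "ffm_kg": subject.ffm_kg,
            "fm_kg": subject.fm_kg,
            "msmr_kj_day": night.summary.msmr_kj_day,
            "momr_kj_day": night.summary.momr_kj_day,
            "mrmr_kj_day": mrmr,
            "smr_ratio": rates.smr_ratio,
            "omr_ratio": rates.omr_ratio,
            "rmr_ratio": rates.rmr_ratio,
            "deficient": rates.deficient,
            "pal": reference.pal(total_ee, mrmr),
            "ea_kcal_kg_ffm_day": reference.energy_availability(
                subject.energy_intake_kcal_day, subject.exercise_ee_kcal_day,
                subject.ffm_kg),
            "spt_min": night.architecture.spt_min,
            "tst_min": night.architecture.tst_min,
            "waso_min": night.architecture.waso_min,
            "sleep_efficiency_pct": night.architecture.sleep_efficiency_pct,
            "sws_rem_ratio_pct": night.architecture.sws_rem_ratio_pct,
            "qc_excluded": night.qc.excluded,
        })
    summaries = pd.DataFrame(rows)

    correlations = calorimetry.pearson_rate_correlations({
        "msmr": summaries["msmr_kj_day"], "momr": summaries["momr_kj_day"],
        "mrmr": summaries["mrmr_kj_day"]})
    anova = stats.five_group_anova({
        g: df["msmr_kj_day"].to_numpy() for g, df in summaries.groupby("group")})
    ancova = stats.adjusted_group_comparison(
        summaries["msmr_kj_day"], summaries["group"],
        summaries["ffm_kg"], summaries["fm_kg"])

    # 16-bin overnight time course, runners vs controls (follicular nights)
    bins = np.array([calorimetry.bin_timecourse(n.measured_ee)
                     for n in nights if n.phase != "luteal"])
    training = np.array(["runner" if "runner" in n.subject.group else "control"
                         for n in nights if n.phase != "luteal"])
    ffm = np.array([n.subject.ffm_kg for n in nights if n.phase != "luteal"])
    fm = np.array([n.subject.fm_kg for n in nights if n.phase != "luteal"])
    timecourse = stats.timecourse_ancova(bins, training, ffm, fm)

    paired = {}
    if luteal_pairs:
        pair_groups: dict[str, list[str]] = {}
        for s in subjects:
            if s.subject_id in luteal_pairs:
                pair_groups.setdefault(s.group, []).append(s.subject_id)
        for grp, ids in pair_groups.items():
            f = [luteal_pairs[i]["follicular"] for i in ids]
            l = [luteal_pairs[i]["luteal"] for i in ids]
            paired[grp] = stats.paired_phase_test(f, l)

    power = stats.rm_power_total_n(stats.PowerSpec())
    from .io import subjects_to_frame

    return StudyResult(
        subjects=subjects_to_frame(subjects),
        nights=nights,
        summaries=summaries,
        correlations=correlations,
        anova_msmr=anova,
        ancova_msmr=ancova,
        timecourse=timecourse,
        paired=paired,
        power=power,
    )
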