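"""Estimated metabolic rates, measured/estimated ratios, and derived
energy-status indices.

Three estimation equations developed for healthy Japanese adults are
implemented: a tissue-organ model for resting metabolic rate (RMR), an
FFM regression for sleeping metabolic rate (SMR), and an FFM/FM/sex
regression for overnight metabolic rate (OMR).  The measured/estimated
RMR ratio below 0.94 classifies a participant as energy deficient (the
cutoff developed for menstrual disturbances).  Also provided: physical
activity level (PAL = total EE / mRMR) and energy availability
(EA = (intake - exercise EE) / FFM).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ReferenceRates",
    "estimate_rmr",
    "estimate_smr",
    "estimate_omr",
    "metabolic_ratios",
    "pal",
    "energy_availability",
    "RMR_RATIO_CUTOFF",
]

#: Measured/estimated RMR below this flags energy deficiency.
RMR_RATIO_CUTOFF = 0.94

#: kJ/day per kg of tissue in the organ-based RMR model.
TISSUE_COEFFICIENTS = {
    "brain": 1004.0,
    "skeletal_muscle": 54.0,
    "bone": 10.0,
    "adipose": 19.0,
    "residual": 180.0,
}

# SMR regression: kJ/day = 77 * FFM + 1815
SMR_SLOPE_PER_KG_FFM = 77.0
SMR_INTERCEPT = 1815.0

# OMR regression: MJ/day = 0.0812*FFM + 0.0213*FM - 0.2125*sex + 1.8175
OMR_FFM = 0.0812
OMR_FM = 0.0213
OMR_SEX = -0.2125
OMR_INTERCEPT = 1.8175


@dataclass
class ReferenceRates:
    """Estimated rates, measured/estimated ratios and energy indices for
    one subject.  Ratio fields are None until the measured rates are
    joined in via :func:`metabolic_ratios`."""

    est_rmr_kj_day: float
    est_smr_kj_day: float
    est_omr_kj_day: float
    rmr_ratio: float | None = None
    smr_ratio: float | None = None
    omr_ratio: float | None = None
    deficient: bool | None = None
    pal: float | None = None
    ea_kcal_kg_ffm_day: float | None = None


def estimate_rmr(tissues) -> float:
    """Organ/tissue RMR estimate, kJ/day.

    ``tissues`` needs attributes brain, skeletal_muscle, bone, adipose,
    residual (kg each); the estimate is their fixed linear combination.
    """
    total = 0.0
    for name, coeff in TISSUE_COEFFICIENTS.items():
        mass = getattr(tissues, name)
        if mass < 0:
            raise ValueError(f"negative {name} mass: {mass}")
        total += coeff * mass
    return total


def estimate_smr(ffm_kg: float) -> float:
    """FFM-based SMR estimate, kJ/day."""
    if ffm_kg < 0:
        raise ValueError(f"negative FFM: {ffm_kg}")
    return SMR_SLOPE_PER_KG_FFM * ffm_kg + SMR_INTERCEPT


def estimate_omr(ffm_kg: float, fm_kg: float, sex_code: int) -> float:
    """FFM/FM/sex OMR estimate, kJ/day (sex_code 1 = male, 2 = female)."""
    if ffm_kg < 0 or fm_kg < 0:
        raise ValueError("FFM and FM must be >= 0")
    if sex_code not in (1, 2):
        raise ValueError(f"sex_code must be 1 (male) or 2 (female), got {sex_code}")
    mj = OMR_FFM * ffm_kg + OMR_FM * fm_kg + OMR_SEX * sex_code + OMR_INTERCEPT
    return mj * 1000.0


def metabolic_ratios(
    measured,
    rates: ReferenceRates,
    cutoff: float = RMR_RATIO_CUTOFF,
) -> ReferenceRates:
    """Fill in measured/estimated ratios and the deficiency flag.

    ``measured`` needs msmr_kj_day / momr_kj_day / mrmr_kj_day
    attributes (a :class:`~somnocal.sleep.MetabolicSummary` fits).
    A ratio exactly at the cutoff is *not* deficient (strict less-than).
    Ratios whose measured value is absent stay None; the deficiency flag
    requires a measured RMR.
    """
    for est in (rates.est_rmr_kj_day, rates.est_smr_kj_day, rates.est_omr_kj_day):
        if est <= 0:
            raise ValueError("estimated rates must be positive")
    rates.smr_ratio = measured.msmr_kj_day / rates.est_smr_kj_day
    rates.omr_ratio = measured.momr_kj_day / rates.est_omr_kj_day
    if measured.mrmr_kj_day is not None:
        rates.rmr_ratio = measured.mrmr_kj_day / rates.est_rmr_kj_day
        rates.deficient = rates.rmr_ratio < cutoff
    return rates


def pal(total_ee_kj_day: float, mrmr_kj_day: float) -> float:
    """Physical activity level: total daily EE divided by measured RMR."""
    if mrmr_kj_day <= 0:
        raise ValueError("measured RMR must be positive")
    return total_ee_kj_day / mrmr_kj_day


def energy_availability(
    energy_intake_kcal_day: float,
    exercise_ee_kcal_day: float,
    ffm_kg: float,
) -> float:
    """Energy availability, kcal per kg FFM per day."""
    if ffm_kg <= 0:
        raise ValueError("FFM must be positive")
    return (energy_intake_kcal_day - exercise_ee_kcal_day) / ffm_kg
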