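"""Energy expenditure and RER from gas exchange, plus run-level QC.

EE is computed from VO2, VCO2 and urinary nitrogen with the Weir
equation; the respiratory exchange ratio (RER) is VCO2/VO2.  The module
also provides the 30-min time-course binning, the supine resting
metabolic rate (mRMR) window, the participant-level exclusion rules
(excess wake, RER above 1.00 during sleep), and the pairwise
correlations between the three measured rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

from .hypnogram import Hypnogram

__all__ = [
    "WeirCoefficients",
    "EESeries",
    "QCReport",
    "weir_ee",
    "bin_timecourse",
    "measure_rmr",
    "qc_exclude",
    "pearson_rate_correlations",
]

KCAL_TO_KJ = 4.184
MINUTES_PER_DAY = 1440.0

#: Length of the overnight sleep segment, minutes (8-h opportunity).
SLEEP_SEGMENT_MIN = 480

#: Supine mRMR protocol: 30 min recorded, first and last 5 min discarded.
RMR_SEGMENT_MIN = 30
RMR_TRIM_MIN = 5


@dataclass(frozen=True)
class WeirCoefficients:
    """Coefficients of the Weir equation, kcal per litre of gas and per
    gram of urinary nitrogen:

        EE_kcal/min = o2 * VO2 + co2 * VCO2 - nitrogen * UN_g/min

    The classic values (3.941, 1.106, 2.17) are the default; alternates
    (e.g. protein-free variants) can be swapped in through run config.
    """

    o2: float = 3.941
    co2: float = 1.106
    nitrogen: float = 2.17


@dataclass
class EESeries:
    """Minute-wise energy expenditure (kJ/min) and RER.

    ``segments`` maps a protocol label ("sleep", "supine_rmr", "sitting")
    to a half-open minute interval [start, stop) into ``ee``.  ``rer`` is
    NaN where VO2 was zero (undefined) or where EE was synthesized
    without gas data.
    """

    ee_kj_min: np.ndarray
    rer: np.ndarray | None = None
    segments: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ee_kj_min = np.asarray(self.ee_kj_min, dtype=float)
        if self.rer is None:
            self.rer = np.full_like(self.ee_kj_min, np.nan)
        else:
            self.rer = np.asarray(self.rer, dtype=float)
        if self.rer.shape != self.ee_kj_min.shape:
            raise ValueError("rer and ee must have equal length")
        for label, (start, stop) in self.segments.items():
            if not (0 <= start < stop <= len(self.ee_kj_min)):
                raise ValueError(f"segment {label!r} out of range")

    def __len__(self) -> int:
        return len(self.ee_kj_min)

    def segment(self, label: str) -> "EESeries":
        """The sub-series of one protocol segment (its segments map
        contains only that segment, re-anchored at 0)."""
        start, stop = self.segments[label]
        return EESeries(
            self.ee_kj_min[start:stop],
            self.rer[start:stop],
            segments={label: (0, stop - start)},
        )

    def sleep_segment(self) -> "EESeries":
        if "sleep" not in self.segments:
            raise ValueError("series has no sleep segment")
        out = self.segment("sleep")
        if len(out) != SLEEP_SEGMENT_MIN:
            raise ValueError(
                f"sleep segment must be {SLEEP_SEGMENT_MIN} min, got {len(out)}"
            )
        return out


@dataclass
class QCReport:
    """Participant-level exclusion decision for one night."""

    wake_fraction: float
    mean_sleep_rer: float
    excluded: bool
    reasons: list
    indeterminate: bool = False


def weir_ee(
    gas,
    coefficients: WeirCoefficients | None = None,
    segments: dict | None = None,
) -> EESeries:
    """Weir-equation EE (kJ/min) and RER from a gas-exchange series.

    Urinary nitrogen, measured per day, is spread uniformly over the
    1440 minutes.  RER is NaN for minutes with zero VO2; EE is still
    computed there.
    """
    c = coefficients or WeirCoefficients()
    vo2 = np.asarray(gas.vo2, dtype=float)
    vco2 = np.asarray(gas.vco2, dtype=float)
    un_per_min = gas.urinary_nitrogen_g_day / MINUTES_PER_DAY
    ee_kcal = c.o2 * vo2 + c.co2 * vco2 - c.nitrogen * un_per_min
    with np.errstate(divide="ignore", invalid="ignore"):
        rer = np.where(vo2 > 0, vco2 / np.where(vo2 > 0, vo2, 1.0), np.nan)
    return EESeries(ee_kcal * KCAL_TO_KJ, rer, segments=dict(segments or {}))


def bin_timecourse(ee: EESeries, bin_min: int = 30) -> np.ndarray:
    """Mean EE of consecutive ``bin_min``-minute bins over the sleep
    segment; the default yields the 16-point overnight time course."""
    sleep = ee.sleep_segment()
    n = len(sleep)
    if n % bin_min:
        raise ValueError(f"sleep segment ({n} min) not divisible by {bin_min}")
    return sleep.ee_kj_min.reshape(n // bin_min, bin_min).mean(axis=1)


def measure_rmr(ee: EESeries) -> float:
    """Measured resting metabolic rate, kJ/day.

    Mean EE over the supine segment with the first and last 5 of its 30
    minutes discarded (minutes 5..24 inclusive), scaled to a day.
    """
    if "supine_rmr" not in ee.segments:
        raise ValueError("series has no supine_rmr segment")
    seg = ee.segment("supine_rmr")
    if len(seg) != RMR_SEGMENT_MIN:
        raise ValueError(f"supine segment must be {RMR_SEGMENT_MIN} min, got {len(seg)}")
    retained = seg.ee_kj_min[RMR_TRIM_MIN : RMR_SEGMENT_MIN - RMR_TRIM_MIN]
    if len(retained) < 11:
        raise ValueError("fewer than 11 minutes retained after trimming")
    return float(retained.mean() * MINUTES_PER_DAY)


def qc_exclude(
    hypnogram: Hypnogram,
    ee: EESeries,
    wake_limit: float = 1.0 / 3.0,
    rer_limit: float = 1.00,
) -> QCReport:
    """Apply the participant exclusion rules to one night.

    A night is excluded when the subject was awake for more than a third
    of the sleep period, or the mean RER over the 8-h sleep segment
    exceeded 1.00.  If more than 20% of sleep minutes lack an RER the
    report is marked indeterminate (and not excluded on RER grounds).
    """
    sleep = ee.sleep_segment()
    if hypnogram.duration_min != len(sleep):
        raise ValueError("hypnogram and sleep segment are misaligned")
    counts = hypnogram.stage_epoch_counts()
    wake_fraction = counts["W"] / len(hypnogram)
    rer = sleep.rer
    missing = float(np.mean(np.isnan(rer)))
    indeterminate = missing > 0.20
    mean_rer = float(np.nanmean(rer)) if missing < 1.0 else float("nan")
    reasons = []
    if wake_fraction > wake_limit:
        reasons.append("wake")
    if not indeterminate and mean_rer > rer_limit:
        reasons.append("rer")
    return QCReport(
        wake_fraction=wake_fraction,
        mean_sleep_rer=mean_rer,
        excluded=bool(reasons),
        reasons=reasons,
        indeterminate=indeterminate,
    )


def pearson_rate_correlations(rates: dict) -> dict:
    """Pairwise Pearson correlations between measured metabolic rates.

    ``rates`` maps a rate name (e.g. "msmr", "momr", "mrmr") to a vector
    of per-subject values.  Returns {(a, b): {"r", "p", "defined"}}.
    A rate with zero variance yields an undefined (flagged) correlation.
    """
    names = list(rates)
    arrays = {k: np.asarray(v, dtype=float) for k, v in rates.items()}
    n = {len(v) for v in arrays.values()}
    if len(n) != 1:
        raise ValueError("all rate vectors must have equal length")
    if n.pop() < 3:
        raise ValueError("need at least 3 subjects")
    out = {}
    for a, b in combinations(names, 2):
        x, y = arrays[a], arrays[b]
        if np.std(x) == 0 or np.std(y) == 0:
            out[(a, b)] = {"r": float("nan"), "p": float("nan"), "defined": False}
        else:
            res = sps.pearsonr(x, y)
            out[(a, b)] = {"r": float(res.statistic), "p": float(res.pvalue),
                           "defined": True}
    return out
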