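"""Sleep architecture and sleep-period energy metabolism.

Definitions follow standard polysomnographic conventions:

* sleep onset — first epoch of any sleep stage;
* last awakening — end of the last sleep-stage epoch;
* SPT (sleep period time) — onset to last awakening, interior wake included;
* WASO — wake after sleep onset, within the SPT;
* TST — SPT minus WASO;
* sleep efficiency — 100 * TST / SPT;
* SWS+REM ratio — 100 * (N3 + R minutes) / TST.

The sleeping metabolic rate (mSMR) is the mean EE over the lowest three
consecutive hours within the 8-h sleep period, found by a sliding
180-min window at 1-min steps; the overnight metabolic rate (mOMR) is
the mean over the whole 8 h.  Stage-specific EE uses only minutes whose
two 30-s epochs carry the same stage (the 60-s continuity rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calorimetry import EESeries, MINUTES_PER_DAY
from .hypnogram import EPOCH_SECONDS, Hypnogram, SLEEP_STAGES

__all__ = [
    "SleepArchitecture",
    "MetabolicSummary",
    "score_architecture",
    "stage_mean_ee",
    "sliding_smr",
    "overnight_omr",
    "summarize_night",
]

SMR_WINDOW_MIN = 180


@dataclass
class SleepArchitecture:
    """Night-level sleep metrics; times in minutes from lights off."""

    spt_min: float
    tst_min: float
    waso_min: float
    stage_minutes: dict
    sleep_efficiency_pct: float
    sws_rem_ratio_pct: float
    sleep_onset_min: float
    last_awakening_min: float


@dataclass
class MetabolicSummary:
    """Headline metabolic quantities for one subject-night."""

    msmr_kj_day: float
    momr_kj_day: float
    mrmr_kj_day: float | None = None
    smr_window_start_min: int | None = None
    stage_ee_kj_min: dict = field(default_factory=dict)
    qualifying_minutes: dict = field(default_factory=dict)


def score_architecture(h: Hypnogram) -> SleepArchitecture:
    """Score a hypnogram into the standard architecture metrics."""
    epochs = h.epochs
    asleep = np.nonzero(epochs != "W")[0]
    if len(asleep) == 0:
        raise ValueError("all-wake hypnogram: no sleep onset")
    onset_epoch = asleep[0]
    end_epoch = asleep[-1] + 1  # exclusive
    epoch_min = EPOCH_SECONDS / 60.0
    spt = (end_epoch - onset_epoch) * epoch_min
    within = epochs[onset_epoch:end_epoch]
    waso = float(np.sum(within == "W")) * epoch_min
    tst = spt - waso
    stage_minutes = {
        s: float(np.sum(within == s)) * epoch_min for s in SLEEP_STAGES
    }
    sws_rem = stage_minutes["N3"] + stage_minutes["R"]
    return SleepArchitecture(
        spt_min=spt,
        tst_min=tst,
        waso_min=waso,
        stage_minutes=stage_minutes,
        sleep_efficiency_pct=100.0 * tst / spt,
        sws_rem_ratio_pct=100.0 * sws_rem / tst,
        sleep_onset_min=onset_epoch * epoch_min,
        last_awakening_min=end_epoch * epoch_min,
    )


def stage_mean_ee(ee: EESeries, h: Hypnogram) -> tuple[dict, dict]:
    """Mean EE per sleep/wake stage over qualifying minutes.

    Minute k (half-open [k, k+1) from lights off) qualifies for stage s
    iff both of its 30-s epochs are scored s.  Stages with no qualifying
    minutes are absent from the result rather than reported as zero.

    Returns ``(stage_means, qualifying_minutes)``.
    """
    sleep = ee.sleep_segment()
    minute_stage = h.minute_stages()
    if len(minute_stage) != len(sleep):
        raise ValueError(
            f"hypnogram covers {len(minute_stage)} min but EE covers {len(sleep)}"
        )
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for s in np.unique(minute_stage):
        if s == "":
            continue
        mask = minute_stage == s
        vals = sleep.ee_kj_min[mask]
        ok = np.isfinite(vals)
        if ok.any():
            means[str(s)] = float(vals[ok].mean())
            counts[str(s)] = int(ok.sum())
    return means, counts


def sliding_smr(ee: EESeries, window_min: int = SMR_WINDOW_MIN) -> tuple[float, int]:
    """Measured sleeping metabolic rate: the lowest three-consecutive-hour
    mean EE within the 8-h sleep period, scaled to kJ/day.

    All 180-min windows at 1-min steps are evaluated (301 candidates);
    ties resolve to the earliest window.  Windows containing missing
    (NaN) minutes are skipped; if every window is skipped an error is
    raised.

    Returns ``(msmr_kj_day, window_start_min)``.
    """
    sleep = ee.sleep_segment()
    x = sleep.ee_kj_min
    n = len(x)
    if window_min > n:
        raise ValueError("window longer than sleep segment")
    valid = np.isfinite(x)
    csum = np.cumsum(np.where(valid, x, 0.0))
    ccnt = np.cumsum(valid.astype(int))
    best_mean, best_start = np.inf, None
    for start in range(n - window_min + 1):
        cnt = ccnt[start + window_min - 1] - (ccnt[start - 1] if start else 0)
        if cnt < window_min:
            continue  # window contains missing minutes
        total = csum[start + window_min - 1] - (csum[start - 1] if start else 0)
        mean = total / window_min
        if mean < best_mean:
            best_mean, best_start = mean, start
    if best_start is None:
        raise ValueError("no complete 3-h window in the sleep segment")
    return float(best_mean * MINUTES_PER_DAY), int(best_start)


def overnight_omr(ee: EESeries, max_missing_fraction: float = 0.05) -> float:
    """Overnight metabolic rate: mean EE of the entire 8-h sleep period,
    kJ/day.  Rejects nights missing more than 5% of minutes."""
    sleep = ee.sleep_segment()
    x = sleep.ee_kj_min
    missing = float(np.mean(~np.isfinite(x)))
    if missing > max_missing_fraction:
        raise ValueError(f"{missing:.0%} of sleep minutes missing")
    return float(np.nanmean(x) * MINUTES_PER_DAY)


def summarize_night(
    ee: EESeries,
    h: Hypnogram,
    mrmr_kj_day: float | None = None,
) -> MetabolicSummary:
    """Combine the sleep-period EE metrics into one summary record."""
    msmr, start = sliding_smr(ee)
    momr = overnight_omr(ee)
    stage_ee, qual = stage_mean_ee(ee, h)
    return MetabolicSummary(
        msmr_kj_day=msmr,
        momr_kj_day=momr,
        mrmr_kj_day=mrmr_kj_day,
        smr_window_start_min=start,
        stage_ee_kj_min=stage_ee,
        qualifying_minutes=qual,
    )
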