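"""Plain-text I/O: CSV tables for subjects, hypnograms, gas traces and
EE series, plus the YAML run configuration.

Column layouts are documented in ``docs/data_dictionary.md``.
"""

from __future__ import annotations

from dataclasses import asdict
from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import yaml

from .calorimetry import EESeries
from .chamber import ChamberSpec, GasExchangeSeries, GasTrace
from .cohort import SubjectProfile, TissueMasses
from .hypnogram import EPOCH_SECONDS, Hypnogram

__all__ = [
    "subjects_to_frame", "write_subjects", "read_subjects",
    "write_hypnogram", "read_hypnogram",
    "write_trace", "read_trace",
    "write_gas", "read_gas",
    "write_ee", "read_ee",
    "load_run_config",
]

_TISSUE_COLS = ["brain", "skeletal_muscle", "bone", "adipose", "residual"]


def subjects_to_frame(subjects: list[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = asdict(s)
        tissues = row.pop("tissues")
        if tissues:
            row.update({f"tissue_{k}_kg": v for k, v in tissues.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_subjects(subjects: list[SubjectProfile], path) -> None:
    subjects_to_frame(subjects).to_csv(path, index=False)


def read_subjects(path) -> list[SubjectProfile]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        tissues = None
        if f"tissue_{_TISSUE_COLS[0]}_kg" in r:
            tissues = TissueMasses(**{c: float(r[f"tissue_{c}_kg"]) for c in _TISSUE_COLS})
        kwargs = {k: r[k] for k in (
            "subject_id", "sex_code", "group", "menstrual_status", "phase",
            "body_mass_kg", "height_cm", "ffm_kg", "fm_kg",
            "urinary_nitrogen_g_day", "energy_intake_kcal_day",
            "exercise_ee_kcal_day", "active_ee_kcal_day", "habitual_bedtime",
            "true_smr_kj_day", "true_rmr_kj_day")}
        kwargs["sex_code"] = int(kwargs["sex_code"])
        out.append(SubjectProfile(tissues=tissues, **kwargs))
    return out


def _epoch_clock(lights_off: str, index: int) -> str:
    t0 = datetime.strptime(lights_off, "%H:%M")
    t = t0 + timedelta(seconds=index * EPOCH_SECONDS)
    return t.strftime("%H:%M:%S")


def write_hypnogram(h: Hypnogram, path) -> None:
    df = pd.DataFrame({
        "epoch_index": np.arange(len(h)),
        "clock_time": [_epoch_clock(h.lights_off, i) for i in range(len(h))],
        "stage": h.epochs,
    })
    df.to_csv(path, index=False)


def read_hypnogram(path) -> Hypnogram:
    df = pd.read_csv(path)
    lights_off = str(df["clock_time"].iloc[0])[:5] if "clock_time" in df else "23:00"
    return Hypnogram(df["stage"].to_numpy(dtype="U2"), lights_off=lights_off)


def write_trace(trace: GasTrace, path) -> None:
    pd.DataFrame({
        "time_min": trace.time_min,
        "o2_frac": trace.o2_fraction,
        "co2_frac": trace.co2_fraction,
    }).to_csv(path, index=False)


def read_trace(path, spec: ChamberSpec | None = None) -> GasTrace:
    df = pd.read_csv(path)
    return GasTrace(df["time_min"].to_numpy(), df["o2_frac"].to_numpy(),
                    df["co2_frac"].to_numpy(), spec=spec or ChamberSpec())


def write_gas(gas: GasExchangeSeries, path) -> None:
    pd.DataFrame({
        "minute": np.arange(len(gas)),
        "vo2_l_min": gas.vo2,
        "vco2_l_min": gas.vco2,
        "urinary_nitrogen_g_day": gas.urinary_nitrogen_g_day,
    }).to_csv(path, index=False)


def read_gas(path) -> GasExchangeSeries:
    df = pd.read_csv(path)
    un = float(df["urinary_nitrogen_g_day"].iloc[0]) if "urinary_nitrogen_g_day" in df else 0.0
    return GasExchangeSeries(df["vo2_l_min"].to_numpy(), df["vco2_l_min"].to_numpy(),
                             urinary_nitrogen_g_day=un)


def write_ee(ee: EESeries, path) -> None:
    segment = np.array([""] * len(ee), dtype=object)
    for label, (start, stop) in ee.segments.items():
        segment[start:stop] = label
    pd.DataFrame({
        "minute": np.arange(len(ee)),
        "ee_kj_min": ee.ee_kj_min,
        "rer": ee.rer,
        "segment": segment,
    }).to_csv(path, index=False)


def read_ee(path) -> EESeries:
    df = pd.read_csv(path)
    segments = {}
    if "segment" in df:
        seg = df["segment"].fillna("")
        for label in seg.unique():
            if label:
                idx = np.nonzero((seg == label).to_numpy())[0]
                segments[label] = (int(idx[0]), int(idx[-1]) + 1)
    return EESeries(df["ee_kj_min"].to_numpy(),
                    df["rer"].to_numpy() if "rer" in df else None,
                    segments=segments)


def load_run_config(path) -> dict:
    """Parse a YAML run config; a ``chamber:`` block becomes a
    :class:`ChamberSpec` under key ``"chamber_spec"``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "chamber" in cfg:
        cfg["chamber_spec"] = ChamberSpec(**cfg["chamber"])
    return cfg
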