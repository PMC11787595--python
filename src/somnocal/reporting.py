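"""Small reporting utilities shared by the tables and the CLI."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

__all__ = ["round_half_up", "percent_elevation", "format_summary"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (the convention used for reported
    percentages and rates), not banker's rounding."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent_elevation(reference: float, elevated: float, decimals: int = 1) -> float:
    """Percent elevation of ``elevated`` over ``reference``,
    e.g. luteal over follicular sleeping metabolic rate."""
    if reference == 0:
        raise ValueError("reference value must be nonzero")
    return round_half_up(100.0 * (elevated - reference) / reference, decimals)


def format_summary(summary, architecture=None) -> str:
    """Plain-text block for one subject-night's metabolic summary."""
    lines = [
        f"mSMR  {summary.msmr_kj_day:8.1f} kJ/day  (3-h window from minute "
        f"{summary.smr_window_start_min})",
        f"mOMR  {summary.momr_kj_day:8.1f} kJ/day",
    ]
    if summary.mrmr_kj_day is not None:
        lines.append(f"mRMR  {summary.mrmr_kj_day:8.1f} kJ/day")
    for stage in ("N3", "N2", "N1", "R", "W"):
        if stage in summary.stage_ee_kj_min:
            lines.append(
                f"EE[{stage:>2}] {summary.stage_ee_kj_min[stage]:6.3f} kJ/min "
                f"({summary.qualifying_minutes[stage]} qualifying min)")
    if architecture is not None:
        lines += [
            f"SPT {architecture.spt_min:.1f} min, TST {architecture.tst_min:.1f} min, "
            f"WASO {architecture.waso_min:.1f} min",
            f"sleep efficiency {architecture.sleep_efficiency_pct:.1f}%, "
            f"SWS+REM/TST {architecture.sws_rem_ratio_pct:.1f}%",
        ]
    return "\n".join(lines)
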