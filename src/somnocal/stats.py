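"""Statistical battery for the sleep-metabolism comparisons.

Covers: five-group one-way ANOVA on subject characteristics, paired t
tests between menstrual phases, ANCOVA of group differences with
fat-free mass (FFM) and fat mass (FM) as covariates, the split-plot
(mixed-design) analysis of the 16-bin overnight EE time course, and the
a-priori sample-size computation for a repeated-measures within-between
interaction based on the noncentral F distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "PowerSpec",
    "ComparisonResult",
    "five_group_anova",
    "paired_phase_test",
    "adjusted_group_comparison",
    "timecourse_ancova",
    "rm_power",
    "rm_power_total_n",
]


@dataclass(frozen=True)
class PowerSpec:
    """Settings of the repeated-measures power computation.

    ``f`` is Cohen's effect size f, ``rho`` the correlation among
    repeated measures, ``epsilon`` the nonsphericity correction, ``g``
    the number of groups and ``m`` the number of repeated measures.
    """

    f: float = 0.4
    alpha: float = 0.05
    power_target: float = 0.95
    g: int = 2
    m: int = 16
    rho: float = 0.5
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power_target < 1:
            raise ValueError("power_target must lie in (0, 1)")
        if self.g < 2 or self.m < 2:
            raise ValueError("need at least 2 groups and 2 measures")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")
        if self.f <= 0:
            raise ValueError("effect size f must be positive")


@dataclass
class ComparisonResult:
    """One tested effect: statistic, degrees of freedom and p-value,
    with optional adjusted means / slopes / post-hoc details."""

    effect: str
    statistic: float
    df: tuple
    p_value: float
    adjusted_means: dict = field(default_factory=dict)
    covariate_slopes: dict = field(default_factory=dict)
    details: dict = field(default_factory=dict)


def five_group_anova(groups: dict, posthoc: bool = False) -> ComparisonResult:
    """One-way ANOVA across the study groups (any number >= 2).

    ``groups`` maps a group label to its vector of values.  With
    ``posthoc=True``, unadjusted pairwise Welch-free two-sample t tests
    are attached under ``details['posthoc']``.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for k, a in zip(labels, arrays):
        if len(a) < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    n_total = sum(len(a) for a in arrays)
    df = (len(arrays) - 1, n_total - len(arrays))
    allv = np.concatenate(arrays)
    ss_between = sum(len(a) * (a.mean() - allv.mean()) ** 2 for a in arrays)
    if ss_between == 0:
        # identical group means (e.g. all values equal): no effect by definition
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.f_oneway(*arrays)
    res = ComparisonResult("group", float(stat), df, float(p))
    if posthoc:
        ph = {}
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                t, tp = sps.ttest_ind(arrays[i], arrays[j])
                ph[(labels[i], labels[j])] = {"t": float(t), "p": float(tp)}
        res.details["posthoc"] = ph
        res.details["multiplicity"] = "unadjusted pairwise p-values"
    return res


def paired_phase_test(follicular, luteal) -> ComparisonResult:
    """Two-sided paired t test between menstrual phases (or any paired
    conditions).  Zero-variance differences yield an undefined statistic
    with ``details['defined'] = False``."""
    x = np.asarray(follicular, dtype=float)
    y = np.asarray(luteal, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            # identical pairs: no evidence of any difference
            return ComparisonResult("phase", 0.0, (n - 1,), 1.0,
                                    details={"defined": True})
        return ComparisonResult("phase", float("nan"), (n - 1,), float("nan"),
                                details={"defined": False})
    t, p = sps.ttest_rel(y, x)
    return ComparisonResult("phase", float(t), (n - 1,), float(p),
                            details={"defined": True, "mean_difference": float(d.mean())})


def _ancova_frame(values, group, ffm=None, fm=None) -> pd.DataFrame:
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": pd.Categorical(group)})
    if ffm is not None:
        df["ffm"] = np.asarray(ffm, dtype=float)
    if fm is not None:
        df["fm"] = np.asarray(fm, dtype=float)
    return df


def adjusted_group_comparison(values, group, ffm, fm) -> ComparisonResult:
    """ANCOVA of a per-subject quantity: value ~ group + FFM + FM.

    The group effect is tested after covariate adjustment (type-II sum
    of squares); adjusted group means are evaluated at the covariate
    grand means.  A covariate with no variation is dropped, so the test
    reduces exactly to the unadjusted ANOVA when both are constant.
    Near-collinear covariates set ``details['conditioning_warning']``.
    """
    df = _ancova_frame(values, group, ffm, fm)
    covariates = [c for c in ("ffm", "fm") if np.ptp(df[c]) > 0]
    n_groups = df["group"].nunique()
    n_params = n_groups + len(covariates)
    if len(df) <= n_params:
        raise ValueError("need more observations than model parameters")
    rhs = " + ".join(["C(group)", *covariates])
    fit = smf.ols(f"value ~ {rhs}", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    f_group = float(table.loc["C(group)", "F"])
    p_group = float(table.loc["C(group)", "PR(>F)"])
    df_group = (float(table.loc["C(group)", "df"]), float(table.loc["Residual", "df"]))
    grand = {c: df[c].mean() for c in covariates}
    adj = {}
    for g in df["group"].cat.categories:
        pred = fit.predict(pd.DataFrame({"group": [g], **{k: [v] for k, v in grand.items()}}))
        adj[g] = float(pred.iloc[0])
    slopes = {c: (float(fit.params[c]) if c in covariates else 0.0)
              for c in ("ffm", "fm")}
    warn = bool(np.linalg.cond(fit.model.exog) > 1e8)
    return ComparisonResult(
        "group (FFM/FM adjusted)", f_group, df_group, p_group,
        adjusted_means=adj, covariate_slopes=slopes,
        details={"conditioning_warning": warn, "model": fit},
    )


def timecourse_ancova(
    bins: np.ndarray,
    group,
    ffm=None,
    fm=None,
    posthoc: bool = False,
) -> dict:
    """Split-plot analysis of the binned overnight EE time course.

    ``bins`` is (n_subjects, m) — one row of m time-bin means per
    subject (m = 16 for the 30-min binning of an 8-h night).  The
    between-subject factor is ``group``; FFM/FM covariates, when given,
    enter at the subject level and adjust the group test only.  Within-
    subject effects (time, time x group interaction) are tested against
    the within-subject residual under sphericity.

    Rows containing missing bins are dropped (logged in the result under
    ``"dropped_subjects"``).  Returns a dict with ComparisonResults for
    "interaction", "group" and "time".
    """
    y = np.asarray(bins, dtype=float)
    if y.ndim != 2:
        raise ValueError("bins must be a 2-D (subjects x time) array")
    group = np.asarray(group)
    keep = np.all(np.isfinite(y), axis=1)
    dropped = int(np.sum(~keep))
    y, group = y[keep], group[keep]
    ffm = None if ffm is None else np.asarray(ffm, dtype=float)[keep]
    fm = None if fm is None else np.asarray(fm, dtype=float)[keep]
    n, m = y.shape
    labels = np.unique(group)
    g = len(labels)
    if g < 2 or m < 2 or n <= g:
        raise ValueError("need >= 2 groups, >= 2 bins, and n > g subjects")

    # --- between-subject test on subject means (covariate-adjusted) ---
    subj_mean = y.mean(axis=1)
    if ffm is not None and fm is not None:
        between = adjusted_group_comparison(subj_mean, group, ffm, fm)
        between.effect = "group (FFM/FM adjusted)"
    else:
        between = five_group_anova({k: subj_mean[group == k] for k in labels})
        between.effect = "group"

    # --- within-subject decomposition under sphericity ---
    dev = y - subj_mean[:, None]           # remove subject level
    time_mean = dev.mean(axis=0)           # grand profile
    ss_time = n * float(np.sum(time_mean**2))
    ss_int = 0.0
    resid = 0.0
    for k in labels:
        cell = dev[group == k]
        cell_mean = cell.mean(axis=0)
        ss_int += len(cell) * float(np.sum((cell_mean - time_mean) ** 2))
        resid += float(np.sum((cell - cell_mean) ** 2))
    df_time = m - 1
    df_int = (g - 1) * (m - 1)
    df_err = (n - g) * (m - 1)
    ms_err = resid / df_err

    def f_and_p(ss_effect: float, df_effect: int) -> tuple[float, float]:
        if ss_effect == 0:
            return 0.0, 1.0  # no effect variance at all, e.g. flat profiles
        if ms_err == 0:
            return float("inf"), 0.0
        f = (ss_effect / df_effect) / ms_err
        return f, float(sps.f.sf(f, df_effect, df_err))

    f_int, p_int = f_and_p(ss_int, df_int)
    f_time, p_time = f_and_p(ss_time, df_time)
    result = {
        "interaction": ComparisonResult(
            "time x group", f_int, (df_int, df_err), p_int),
        "time": ComparisonResult(
            "time", f_time, (df_time, df_err), p_time),
        "group": between,
        "dropped_subjects": dropped,
    }
    if posthoc and g == 2:
        a, b = labels
        ph = []
        for j in range(m):
            t, p = sps.ttest_ind(y[group == a, j], y[group == b, j])
            ph.append({"bin": j, "t": float(t), "p": float(p)})
        result["posthoc"] = ph
        result["multiplicity"] = "per-bin p-values are unadjusted"
    return result


def rm_power(n_total: int, spec: PowerSpec) -> float:
    """Achieved power of the within-between interaction test at total
    sample size ``n_total`` (equal groups), via the noncentral F
    distribution with

        lambda = N * f^2 * m * epsilon / (1 - rho)
        df1    = (g - 1)(m - 1) * epsilon
        df2    = (N - g)(m - 1) * epsilon
    """
    lam = n_total * spec.f**2 * spec.m * spec.epsilon / (1.0 - spec.rho)
    df1 = (spec.g - 1) * (spec.m - 1) * spec.epsilon
    df2 = (n_total - spec.g) * (spec.m - 1) * spec.epsilon
    if df2 < 1:
        return 0.0
    crit = sps.f.ppf(1.0 - spec.alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def rm_power_total_n(spec: PowerSpec, n_cap: int = 10**6) -> dict:
    """Smallest total N (divisible by the number of groups) whose
    within-between interaction power reaches the target.

    Returns ``{"total_n", "per_group", "power"}``.  Raises if the target
    is unreachable below ``n_cap``.
    """
    n = 2 * spec.g  # smallest equal-group N with positive error df
    while n <= n_cap:
        p = rm_power(n, spec)
        if p >= spec.power_target:
            return {"total_n": n, "per_group": n // spec.g, "power": p}
        n += spec.g
    raise ValueError(f"power target {spec.power_target} unreachable below N = {n_cap}")
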