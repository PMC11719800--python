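"""Group-level endpoints: growth-delay statistics and progression-free survival.

Growth delay is the difference between a treated animal's tumor growth time
(time to 3x the irradiation volume V0) and the mean growth time of untreated
controls; per arm we report mean, SD, the half-width of the t-based 95% CI,
and two-tailed unpaired t-tests.  Progression-free survival (PFS) is the
time from irradiation to the model-defined start of regrowth; arms are
summarized with the Kaplan-Meier product-limit estimator and compared with
pairwise Mantel-Cox log-rank tests.

The KM estimate and the unstratified log-rank test are delegated to
lifelines; the stratified Mantel-Cox variant (observed-minus-expected summed
across strata) is computed here directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "DelayResult",
    "SurvivalRecord",
    "KMCurve",
    "LogRankResult",
    "growth_delay",
    "unpaired_t_test",
    "km_estimate",
    "logrank_test",
    "build_pfs_dataset",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """(time, event) pair for PFS: event=1 regrowth started, 0 censored."""

    mouse_id: str
    arm: str
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError("time must be positive")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass(frozen=True)
class DelayResult:
    """Per-arm growth-delay summary.

    ``ci95_halfwidth`` is the half-width of the t-based 95% confidence
    interval of the mean delay.  Two p-values are reported because either
    reading of a "treated vs control" test is defensible: ``p_vs_control``
    compares treated and control growth times (two-sample), and
    ``p_delay_vs_zero`` tests the per-mouse delays against zero
    (one-sample).
    """

    arm: str
    per_mouse_growth_times: tuple
    per_mouse_delays: tuple
    mean_delay: float
    sd: float
    ci95_halfwidth: float
    p_vs_control: float
    p_delay_vs_zero: float
    n: int
    n_censored: int = 0


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate for one arm."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    p: float
    groups: tuple


def unpaired_t_test(a, b) -> tuple[float, float]:
    """Classic two-tailed unpaired (pooled-variance Student) t-test.

    Degenerate samples: both variances zero with equal means gives
    (0.0, 1.0); zero pooled variance with unequal means gives
    (+/-inf, 0.0) as the limiting marker.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def growth_delay(treated_times, control_times, arm: str = "",
                 n_censored: int = 0) -> DelayResult:
    """Growth-delay statistics of a treated arm against controls.

    Each treated animal's delay is its growth time minus the mean control
    growth time (arms are independent; no pairing exists).  Censored animals
    must already be excluded from ``treated_times`` and counted in
    ``n_censored``.
    """
    treated = np.asarray(treated_times, dtype=float)
    control = np.asarray(control_times, dtype=float)
    if control.size == 0:
        raise ValueError("control_times must be nonempty")
    if treated.size == 0:
        raise ValueError(
            "no uncensored treated growth times: delay undefined "
            f"({n_censored} censored)"
        )
    delays = treated - control.mean()
    n = delays.size
    mean = float(delays.mean())
    sd = float(delays.std(ddof=1)) if n > 1 else 0.0
    ci = float(sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)) if n > 1 else 0.0
    if treated.size >= 2 and control.size >= 2:
        _, p_two = unpaired_t_test(treated, control)
    else:
        p_two = float("nan")
    if n >= 2 and sd > 0:
        p_zero = float(sps.ttest_1samp(delays, 0.0).pvalue)
    elif n >= 2:
        p_zero = 1.0 if mean == 0 else 0.0
    else:
        p_zero = float("nan")
    return DelayResult(
        arm=arm,
        per_mouse_growth_times=tuple(float(x) for x in treated),
        per_mouse_delays=tuple(float(x) for x in delays),
        mean_delay=mean,
        sd=sd,
        ci95_halfwidth=ci,
        p_vs_control=p_two,
        p_delay_vs_zero=p_zero,
        n=int(n),
        n_censored=int(n_censored),
    )


def km_estimate(records: list[SurvivalRecord]) -> KMCurve:
    """Kaplan-Meier product-limit estimate with right censoring.

    The median is the smallest time at which the estimate drops to <= 0.5,
    None if the curve never reaches it.
    """
    if not records:
        raise ValueError("records must be nonempty")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    t = kmf.survival_function_.index.to_numpy(dtype=float)
    at_risk = table["at_risk"].reindex(t).to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if not np.isfinite(med) else float(med)
    return KMCurve(times=t, survival=surv, at_risk=at_risk, median=median)


def _stratified_mantel_cox(times, events, groups, strata):
    """Sum observed-minus-expected and hypergeometric variance over strata."""
    oe_sum = 0.0
    var_sum = 0.0
    for s in np.unique(strata):
        m = strata == s
        t_s, e_s, g_s = times[m], events[m], groups[m]
        for t in np.unique(t_s[e_s == 1]):
            at_risk = t_s >= t
            n = at_risk.sum()
            n1 = (at_risk & (g_s == 1)).sum()
            d = ((t_s == t) & (e_s == 1)).sum()
            d1 = ((t_s == t) & (e_s == 1) & (g_s == 1)).sum()
            oe_sum += d1 - d * n1 / n
            if n > 1:
                var_sum += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return oe_sum, var_sum


def logrank_test(
    a: list[SurvivalRecord],
    b: list[SurvivalRecord],
    strata: dict[str, object] | None = None,
) -> LogRankResult:
    """Mantel-Cox log-rank test between two arms (chi-square, 1 df).

    With ``strata`` (a mapping mouse_id -> stratum label) the
    observed-minus-expected sums and variances are accumulated within each
    stratum and combined; a single stratum reduces to the plain test.  Ties
    are grouped at identical event times with the hypergeometric variance.
    """
    if not a or not b:
        raise ValueError("both groups must be nonempty")
    n_events = sum(r.event for r in a) + sum(r.event for r in b)
    if n_events == 0:
        raise ValueError("no events in either group: log-rank undefined")
    if strata is None:
        res = _ll_logrank(
            np.array([r.time for r in a]),
            np.array([r.time for r in b]),
            event_observed_A=np.array([r.event for r in a]),
            event_observed_B=np.array([r.event for r in b]),
        )
        chi2, p = float(res.test_statistic), float(res.p_value)
    else:
        recs = list(a) + list(b)
        times = np.array([r.time for r in recs], dtype=float)
        events = np.array([r.event for r in recs], dtype=int)
        groups = np.array([0] * len(a) + [1] * len(b), dtype=int)
        strat = np.array([strata.get(r.mouse_id, 0) for r in recs])
        oe, var = _stratified_mantel_cox(times, events, groups, strat)
        if var == 0:
            chi2, p = 0.0, 1.0
        else:
            chi2 = float(oe * oe / var)
            p = float(sps.chi2.sf(chi2, df=1))
    groups_lbl = (a[0].arm, b[0].arm)
    return LogRankResult(chi2=chi2, p=p, groups=groups_lbl)


def build_pfs_dataset(records, fits, followup_cap: float = 90.0
                      ) -> list[SurvivalRecord]:
    """Turn per-mouse regrowth fits into PFS (time, event) records.

    The event time is the fitted regrowth-start day when it exists and does
    not exceed the follow-up cap (event=1); otherwise the animal is censored
    at min(last follow-up day, cap).
    """
    out = []
    for rec, fit in zip(records, fits):
        start = None if fit is None else fit.regrowth_start_day
        if start is not None and start <= followup_cap:
            out.append(SurvivalRecord(rec.mouse_id, rec.arm, float(start), 1))
        else:
            last = rec.last_followup_day
            if last is None:
                last = rec.measurements[-1].day if rec.measurements else followup_cap
            out.append(
                SurvivalRecord(rec.mouse_id, rec.arm,
                               float(min(last, followup_cap)), 0)
            )
    return out
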