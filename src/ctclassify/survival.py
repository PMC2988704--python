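"""Survival-based validation of a binary prognosis classification.

A prognosis classifier is only useful if the groups it calls actually
separate in progression-free survival.  This module wraps the standard
toolkit: Kaplan-Meier product-limit curves with 95% pointwise bands,
the two-group log-rank test, and a univariate Cox proportional-hazards
hazard ratio with Wald inference.  The heavy lifting is delegated to
``lifelines``; results are repackaged into the project's typed records.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .models import HazardRatioResult, KMEstimate, LogRankResult, SurvivalRecord

__all__ = ["cox_hr", "km_estimate", "logrank_test", "median_survival"]


def _subset(
    records: Iterable[SurvivalRecord], group: Optional[str]
) -> list[SurvivalRecord]:
    recs = list(records)
    if group is not None:
        recs = [r for r in recs if r.group_label == group]
    return recs


def km_estimate(
    records: Iterable[SurvivalRecord],
    group: Optional[str] = None,
) -> KMEstimate:
    """Kaplan-Meier product-limit estimate with 95% confidence bands.

    Restricts to ``group`` when given (matching ``group_label``).  The
    bands are Greenwood-based on the log(−log) scale (the "exponential
    Greenwood" construction), which keeps them inside [0, 1].
    """
    recs = _subset(records, group)
    if not recs:
        raise ValueError(f"no survival records in group {group!r}")
    times = [r.time for r in recs]
    events = [r.event for r in recs]
    kmf = KaplanMeierFitter()
    kmf.fit(times, events, label="S")
    sf = kmf.survival_function_["S"]
    ci = kmf.confidence_interval_survival_function_
    grid = sf.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).ffill().astype(int)
    return KMEstimate(
        group_label=group,
        times=grid.tolist(),
        survival=sf.to_numpy(dtype=float).tolist(),
        ci_low=ci.iloc[:, 0].to_numpy(dtype=float).tolist(),
        ci_high=ci.iloc[:, 1].to_numpy(dtype=float).tolist(),
        n_at_risk=at_risk.tolist(),
    )


def logrank_test(
    records: Iterable[SurvivalRecord],
    group_a: str,
    group_b: str,
) -> LogRankResult:
    """Two-group log-rank comparison (chi-square with 1 df).

    The statistic is the squared observed-minus-expected event count in
    one group over its hypergeometric variance, summed over the risk
    sets at each distinct event time; it is symmetric in the two group
    labels.
    """
    a = _subset(records, group_a)
    b = _subset(records, group_b)
    if not a or not b:
        empty = group_a if not a else group_b
        raise ValueError(f"group {empty!r} has no subjects")
    if not any(r.event for r in a + b):
        raise ValueError("no events observed in either group")
    res = _ll_logrank(
        [r.time for r in a],
        [r.time for r in b],
        event_observed_A=[r.event for r in a],
        event_observed_B=[r.event for r in b],
    )
    chi2 = float(res.test_statistic)
    return LogRankResult(
        chi_square=max(chi2, 0.0),
        p_value=float(res.p_value),
        groups=(group_a, group_b),
        df=1,
    )


def cox_hr(
    records: Iterable[SurvivalRecord],
    exposed_group: str,
) -> HazardRatioResult:
    """Univariate Cox proportional-hazards hazard ratio.

    The single covariate is membership of ``exposed_group`` (1) versus
    everything else (0); the reported HR is the instantaneous event-rate
    ratio of exposed over baseline.  Ties are handled by the Efron
    approximation; the CI and p-value are Wald-based.  Monotone
    separation of the groups makes the partial likelihood unbounded and
    raises a convergence error.
    """
    recs = list(records)
    indicator = [1 if r.group_label == exposed_group else 0 for r in recs]
    if len(set(indicator)) < 2:
        raise ValueError("both exposure levels must be present")
    if sum(r.event for r in recs) < 2:
        raise ValueError("need at least 2 events to fit a hazard ratio")
    frame = pd.DataFrame(
        {
            "time": [r.time for r in recs],
            "event": [int(r.event) for r in recs],
            "exposed": indicator,
        }
    )
    cph = CoxPHFitter()
    try:
        with np.errstate(all="ignore"):
            cph.fit(frame, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ValueError(
            "Cox model did not converge (monotone separation of the groups "
            f"is the usual cause): {exc}"
        ) from exc
    row = cph.summary.loc["exposed"]
    coef, se = float(row["coef"]), float(row["se(coef)"])
    if not math.isfinite(coef) or not math.isfinite(se):
        raise ValueError("Cox fit produced non-finite estimates")
    z = 1.959963984540054  # standard normal 97.5% quantile
    return HazardRatioResult(
        hr=math.exp(coef),
        ci_low=math.exp(coef - z * se),
        ci_high=math.exp(coef + z * se),
        p_value=float(row["p"]),
    )


def median_survival(km: KMEstimate) -> Optional[float]:
    """Smallest time at which survival drops to 0.5 or below.

    Returns ``None`` when the curve never reaches 0.5 ("not reached").
    """
    for t, s in zip(km.times, km.survival):
        if s <= 0.5:
            return float(t)
    return None
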