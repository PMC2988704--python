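"""Quality control of real-time PCR assays.

The delta-delta Ct method assumes every target assay amplifies with
(approximately) the same efficiency as the reference assay.  Efficiency
is estimated from a standard curve — Ct regressed on log10(input
amount) over a serial dilution — via E = 10^(−1/slope) − 1, and the
efficiency match is checked directly on the slope of ΔCt (target −
reference) against log10(input): a matched pair gives a flat line, and
the assay passes when |slope| < 0.1 cycles per decade.

Replicate wells are aggregated by mean; the replicate range (max − min)
drives a warn flag, and negative-control wells must stay quiet
(undetermined, or Ct at least 37 cycles).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .models import (
    AggregatedCt,
    CtWell,
    DilutionSeries,
    EfficiencyMatchResult,
    NegativeControlReport,
    StandardCurveFit,
)

__all__ = [
    "aggregate_replicates",
    "efficiency_match",
    "fit_standard_curve",
    "negative_control_qc",
]


def fit_standard_curve(series: DilutionSeries) -> StandardCurveFit:
    """Fit Ct against log10(input amount) by ordinary least squares.

    Requires at least three dilution points with determined Ct.  The
    amplification efficiency follows from the slope; a value outside the
    nominal [0, 1] range is still reported (``efficiency_nominal`` is
    False on the result) since noisy fits can exceed perfect doubling.
    """
    amounts = series.amounts
    cts = series.cts
    ok = np.isfinite(cts)
    if ok.sum() < 3:
        raise ValueError(
            f"{series.gene_id}: need >= 3 determined dilution points, have {ok.sum()}"
        )
    x = np.log10(amounts[ok])
    y = cts[ok]
    if np.ptp(x) == 0:
        raise ValueError(f"{series.gene_id}: zero variance in input amounts")
    fit = sps.linregress(x, y)
    efficiency = 10.0 ** (-1.0 / fit.slope) - 1.0
    return StandardCurveFit(
        gene_id=series.gene_id,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(efficiency),
        r_squared=float(fit.rvalue**2),
    )


def efficiency_match(
    target: DilutionSeries,
    reference: DilutionSeries,
    criterion: float = 0.1,
) -> EfficiencyMatchResult:
    """Check that a target assay's efficiency matches the reference assay.

    Both series must be measured on the same dilution ladder.  ΔCt is
    computed per dilution point, regressed on log10(input amount), and
    the assay passes when the absolute slope is below ``criterion``.
    """
    a_t, a_r = target.amounts, reference.amounts
    if a_t.shape != a_r.shape or not np.allclose(a_t, a_r, rtol=1e-9, atol=0.0):
        raise ValueError(
            f"{target.gene_id} vs {reference.gene_id}: dilution ladders differ"
        )
    dct = target.cts - reference.cts
    ok = np.isfinite(dct)
    if ok.sum() < 3:
        raise ValueError("need >= 3 points with both Ct values determined")
    fit = sps.linregress(np.log10(a_t[ok]), dct[ok])
    slope = float(fit.slope)
    return EfficiencyMatchResult(
        gene_id=target.gene_id,
        delta_ct_slope=slope,
        criterion=criterion,
        passes=abs(slope) < criterion,
    )


def aggregate_replicates(
    wells: Iterable[CtWell],
    range_warn: float = 0.5,
) -> list[AggregatedCt]:
    """Aggregate replicate wells into one Ct per (sample, gene).

    Negative-control wells are not aggregated (see
    :func:`negative_control_qc`).  Undetermined replicates are dropped
    from the mean; a group whose replicates are all undetermined fails
    QC.  The flag is ``warn`` when the replicate range exceeds
    ``range_warn`` cycles or when some (but not all) replicates were
    undetermined.
    """
    groups: dict[tuple[str, str], list[CtWell]] = defaultdict(list)
    for w in wells:
        if w.role == "negative_control":
            continue
        groups[(w.sample_id, w.gene_id)].append(w)
    out: list[AggregatedCt] = []
    for (sample, gene), group in groups.items():
        cts = np.array([w.ct for w in group if w.ct is not None], dtype=float)
        n = len(group)
        if cts.size == 0:
            out.append(
                AggregatedCt(
                    sample_id=sample, gene_id=gene, ct_mean=None,
                    ct_range=0.0, n_replicates=n, qc_flag="fail",
                )
            )
            continue
        ct_range = float(cts.max() - cts.min())
        flag = "pass"
        if ct_range > range_warn or cts.size < n:
            flag = "warn"
        out.append(
            AggregatedCt(
                sample_id=sample, gene_id=gene, ct_mean=float(cts.mean()),
                ct_range=ct_range, n_replicates=n, qc_flag=flag,
            )
        )
    return out


def negative_control_qc(
    wells: Iterable[CtWell],
    min_ct: float = 37.0,
) -> NegativeControlReport:
    """Screen negative-control wells for contamination.

    A quiet negative control is undetermined or has Ct >= ``min_ct``
    (background-level amplification); any control below that threshold
    indicates contamination and fails the plate.  With no control wells
    present the report passes vacuously, with a warning.
    """
    controls = [w for w in wells if w.role == "negative_control"]
    if not controls:
        warnings.warn("no negative-control wells present; vacuous pass", stacklevel=2)
        return NegativeControlReport(passed=True, min_ct=min_ct, n_controls=0)
    failing = [w for w in controls if w.ct is not None and w.ct < min_ct]
    return NegativeControlReport(
        passed=not failing,
        min_ct=min_ct,
        n_controls=len(controls),
        failing_wells=failing,
    )
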