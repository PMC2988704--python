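"""Conversion of a linear expression classifier to a ΔCt classifier.

A linear classifier on log-normalized relative expression,

    PC1(x) = sum_i a_i * en_i(x),

can be rewritten in terms of cycle thresholds.  With amplification
efficiency E (0 <= E <= 1, shared across well-matched assays), relative
expression of gene i in sample x against a control sample c is

    er_i(x) = (1 + E) ** -(Ct_i(x) - Ct_i(c)),

and the log-normalized expression

    en_i(x) = log10(er_i(x) / er_ref(x))
            = -log10(1+E) * (Ct_i(x) - Ct_ref(x))
            + log10(1+E) * (Ct_i(c) - Ct_ref(c)).

Substituting into the weighted sum shows the classifier score is an
affine function of the Ct-based score

    PC1_rt(x) = sum_i a_i * ΔCt_i(x),        ΔCt_i(x) = Ct_i(x) - Ct_ref(x),

namely PC1(x) = beta1 * PC1_rt(x) + beta0 with beta1 = -log10(1+E) and
beta0 collecting every control-sample term.  Both coefficients are
fitted by ordinary least squares on samples measured on both platforms,
so neither E nor a physical control sample is needed at scoring time.

Per-gene cross-platform agreement (Pearson r, slope and intercept of the
regression of platform log expression on -ΔCt) is computed alongside;
genes showing no correlation are eliminated from the diagnostic set
before the calibration is fitted.  Errors of measurement that are
independent across genes largely cancel in the weighted sum, which is
why the composite score correlates across platforms far better than any
individual gene — and why conversion is done at the score level.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import (
    AggregatedCt,
    CalibrationModel,
    ClassifierSpec,
    ExpressionMatrix,
    PerGeneStat,
    PrognosisCall,
)

__all__ = [
    "MissingGeneError",
    "MissingReferenceError",
    "calibrate",
    "delta_ct",
    "filter_genes",
    "fit_conversion",
    "log_normalized_expression",
    "pc1_rt",
    "per_gene_stats",
    "relative_expression",
    "score_and_classify",
]


class MissingReferenceError(ValueError):
    """A sample lacks a usable reference-gene measurement."""


class MissingGeneError(ValueError):
    """A weighted gene is absent (or unmeasured) where it is required."""


def _as_frame(x: Union[ExpressionMatrix, pd.DataFrame]) -> pd.DataFrame:
    return x.frame if isinstance(x, ExpressionMatrix) else x


def delta_ct(
    aggregates: Iterable[AggregatedCt],
    reference_gene: str,
) -> pd.DataFrame:
    """Build the ΔCt matrix (genes x samples) from aggregated Ct values.

    ΔCt_i(x) = Ct_i(x) − Ct_ref(x).  QC-failed aggregates are treated as
    missing (NaN in the result); every sample must carry a non-failed
    reference-gene measurement or :class:`MissingReferenceError` is
    raised naming the offending sample(s).  The reference gene itself is
    excluded from the rows.
    """
    rows: dict[tuple[str, str], float] = {}
    samples: list[str] = []
    genes: list[str] = []
    for agg in aggregates:
        if agg.sample_id not in samples:
            samples.append(agg.sample_id)
        if agg.gene_id not in genes:
            genes.append(agg.gene_id)
        if agg.qc_flag != "fail" and agg.ct_mean is not None:
            rows[(agg.gene_id, agg.sample_id)] = agg.ct_mean
    if reference_gene not in genes:
        raise MissingReferenceError(
            f"reference gene {reference_gene!r} absent from the Ct data"
        )
    missing_ref = [s for s in samples if (reference_gene, s) not in rows]
    if missing_ref:
        raise MissingReferenceError(
            f"no passing reference-gene ({reference_gene!r}) measurement for "
            f"sample(s): {missing_ref}"
        )
    target_genes = [g for g in genes if g != reference_gene]
    out = pd.DataFrame(np.nan, index=target_genes, columns=samples, dtype=float)
    for sample in samples:
        ref_ct = rows[(reference_gene, sample)]
        for gene in target_genes:
            ct = rows.get((gene, sample))
            if ct is not None:
                out.loc[gene, sample] = ct - ref_ct
    return out


def relative_expression(ct_x: float, ct_c: float, efficiency: float) -> float:
    """Relative expression against a control sample: (1+E)^-(Ct_x - Ct_c)."""
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"efficiency must lie in [0, 1], got {efficiency}")
    return (1.0 + efficiency) ** -(ct_x - ct_c)


def log_normalized_expression(
    delta_ct_x: float, delta_ct_c: float, efficiency: float
) -> float:
    """Common-log normalized expression from sample and control ΔCt.

    en = −log10(1+E)·ΔCt(x) + log10(1+E)·ΔCt(c); equal ΔCt gives 0.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError(f"efficiency must lie in [0, 1], got {efficiency}")
    lam = math.log10(1.0 + efficiency)
    return -lam * delta_ct_x + lam * delta_ct_c


def _weighted_score(dct: pd.DataFrame, weights: Mapping[str, float]) -> pd.Series:
    missing = [g for g in weights if g not in dct.index]
    if missing:
        raise MissingGeneError(f"gene(s) absent from ΔCt matrix: {missing}")
    sub = dct.loc[list(weights)]
    if sub.isna().any().any():
        holes = [
            f"{g}/{s}"
            for g in sub.index
            for s in sub.columns
            if pd.isna(sub.loc[g, s])
        ]
        raise MissingGeneError(f"missing ΔCt measurement(s): {holes}")
    w = pd.Series(dict(weights), dtype=float)
    return sub.mul(w, axis=0).sum(axis=0)


def pc1_rt(dct: pd.DataFrame, spec: ClassifierSpec) -> pd.Series:
    """Ct-based classifier score: PC1_rt(x) = sum_i a_i * ΔCt_i(x).

    Every weighted gene must be present and measured for every sample;
    missing measurements raise rather than silently dropping terms.
    """
    return _weighted_score(dct, spec.weights)


def calibrate(
    pc1_original: pd.Series,
    pc1_rt_scores: pd.Series,
) -> tuple[float, float, float]:
    """Fit PC1 = beta1 * PC1_rt + beta0 by ordinary least squares.

    Returns (beta1, beta0, pearson_r).  Both inputs must cover the same
    samples (at least three) and the Ct-based scores must vary.
    """
    if set(pc1_original.index) != set(pc1_rt_scores.index):
        raise ValueError("sample sets of the two score series differ")
    x = pc1_rt_scores.reindex(pc1_original.index).to_numpy(dtype=float)
    y = pc1_original.to_numpy(dtype=float)
    if x.size < 3:
        raise ValueError(f"need >= 3 paired samples, have {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in PC1_rt scores; cannot calibrate")
    fit = sps.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


def per_gene_stats(
    expr: Union[ExpressionMatrix, pd.DataFrame],
    dct: pd.DataFrame,
    min_samples: int = 3,
) -> list[PerGeneStat]:
    """Cross-platform statistics per gene.

    For every gene shared between the expression matrix and the ΔCt
    matrix: Pearson correlation between platform log expression and
    −ΔCt, and slope/intercept of the regression of log expression on
    −ΔCt.  The −ΔCt orientation makes a well-behaved gene's slope
    positive with theoretical value log10(1+E) (log10(2) ≈ 0.30 at
    perfect efficiency).  Genes with fewer than ``min_samples`` shared
    determined measurements are excluded with a warning.
    """
    eframe = _as_frame(expr)
    shared_genes = [g for g in eframe.index if g in dct.index]
    shared_samples = [s for s in eframe.columns if s in dct.columns]
    stats: list[PerGeneStat] = []
    for gene in shared_genes:
        y = eframe.loc[gene, shared_samples].to_numpy(dtype=float)
        x = -dct.loc[gene, shared_samples].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_samples:
            warnings.warn(
                f"gene {gene!r} has fewer than {min_samples} shared samples; "
                "excluded from per-gene statistics",
                stacklevel=2,
            )
            continue
        fit = sps.linregress(x[ok], y[ok])
        stats.append(
            PerGeneStat(
                gene_id=gene,
                correlation=float(np.clip(fit.rvalue, -1.0, 1.0)),
                slope=float(fit.slope),
                intercept=float(fit.intercept),
            )
        )
    return stats


def filter_genes(
    stats: Sequence[PerGeneStat],
    r_min: float = 0.2,
) -> tuple[list[str], list[str]]:
    """Split genes into (retained, removed) by cross-platform correlation.

    A gene exhibiting no correlation between platforms cannot carry
    information through the conversion, so genes with Pearson r below
    ``r_min`` are removed from the diagnostic set.  Input order is
    preserved in both lists.
    """
    if not stats:
        raise ValueError("per-gene statistics must be non-empty")
    retained = [s.gene_id for s in stats if s.correlation >= r_min]
    removed = [s.gene_id for s in stats if s.correlation < r_min]
    return retained, removed


def fit_conversion(
    expr: Union[ExpressionMatrix, pd.DataFrame],
    dct: pd.DataFrame,
    spec: ClassifierSpec,
    r_min: float = 0.2,
) -> CalibrationModel:
    """Full learning-set calibration: stats, gene filtering, regression.

    Computes per-gene cross-platform statistics for the classifier's
    genes, removes genes with correlation below ``r_min``, then fits the
    affine calibration between the original-platform score and the
    Ct-based score, both restricted to the retained genes.
    """
    eframe = _as_frame(expr)
    missing = [g for g in spec.weights if g not in eframe.index or g not in dct.index]
    if missing:
        raise MissingGeneError(
            f"classifier gene(s) absent from the learning data: {missing}"
        )
    stats = per_gene_stats(eframe.loc[list(spec.weights)], dct)
    retained, removed = filter_genes(stats, r_min=r_min)
    if not retained:
        raise ValueError("every classifier gene was removed by the correlation filter")
    weights_kept = {g: spec.weights[g] for g in retained}
    shared_samples = [s for s in eframe.columns if s in dct.columns]
    rt_scores = _weighted_score(dct[shared_samples], weights_kept)
    w = pd.Series(weights_kept, dtype=float)
    original = eframe.loc[retained, shared_samples].mul(w, axis=0).sum(axis=0)
    beta1, beta0, r = calibrate(original, rt_scores)
    return CalibrationModel(
        beta1=beta1,
        beta0=beta0,
        pearson_r=r,
        retained_genes=retained,
        removed_genes=removed,
        per_gene_stats=stats,
        reference_gene=spec.reference_gene,
        notes=f"fitted on {len(shared_samples)} samples; r_min={r_min}",
    )


def score_and_classify(
    dct: pd.DataFrame,
    spec: ClassifierSpec,
    cal: CalibrationModel,
) -> list[PrognosisCall]:
    """Score samples with the converted classifier and call prognosis.

    PC1(x) = beta1 * PC1_rt(x) + beta0 over the calibration's retained
    genes; a sample is called poor when its PC1 score lies on the
    classifier's poor-prognosis side of the threshold.  A score exactly
    at the threshold is assigned to the poor side (conservative for a
    prognosis screen).
    """
    known = set(cal.retained_genes) | set(cal.removed_genes)
    unknown = [g for g in known if g not in spec.weights]
    if unknown:
        raise MissingGeneError(
            f"calibration covers gene(s) absent from the classifier: {unknown}"
        )
    weights_kept = {g: spec.weights[g] for g in cal.retained_genes}
    rt = _weighted_score(dct, weights_kept)
    calls: list[PrognosisCall] = []
    for sample in dct.columns:
        rt_score = float(rt[sample])
        score = cal.beta1 * rt_score + cal.beta0
        if spec.poor_prognosis_side == "above":
            poor = score >= spec.threshold
        else:
            poor = score <= spec.threshold
        calls.append(
            PrognosisCall(
                sample_id=sample,
                pc1_rt_score=rt_score,
                pc1_score=score,
                group="poor" if poor else "good",
            )
        )
    return calls
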