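"""Reference-gene selection for the delta-delta Ct method.

The ΔCt denominator should be a gene whose expression is near-constant
across the target tissue.  Rather than trusting a housekeeping gene, the
candidates are taken from the profiling data itself: genes whose
expression pattern across samples tracks the per-sample median pattern
are, by construction, the least-changing genes in that tissue.  The
final choice among candidates is made on re-measured quantities (e.g.
real-time PCR of a pilot sample panel): the candidate with the smallest
standard deviation across samples wins.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .models import CandidateRanking, ExpressionMatrix, ReferenceChoice

__all__ = ["median_profile", "rank_candidates", "select_reference"]


def _as_frame(matrix: Union[ExpressionMatrix, pd.DataFrame]) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.frame
    return matrix


def median_profile(matrix: Union[ExpressionMatrix, pd.DataFrame]) -> pd.Series:
    """Per-sample median expression across genes.

    Returns a Series indexed by sample id: for each sample (column) the
    median over all genes of that column.
    """
    frame = _as_frame(matrix)
    if frame.empty:
        raise ValueError("cannot take the median profile of an empty matrix")
    return frame.median(axis=0)


def rank_candidates(
    matrix: Union[ExpressionMatrix, pd.DataFrame],
    k: int = 12,
    center: bool = True,
) -> CandidateRanking:
    """Rank genes by similarity of their profile to the median profile.

    The distance of a gene is the root-mean-square deviation of its
    per-sample profile from the median profile.  With ``center=True``
    (default) each profile — gene and median alike — first has its own
    mean subtracted, so similarity concerns the *shape* of the pattern
    across samples and a constant expression offset does not penalise a
    gene.  Ties are broken by lexicographic gene id.
    """
    frame = _as_frame(matrix)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > frame.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({frame.shape[0]})")
    med = median_profile(frame)
    profiles = frame.to_numpy(dtype=float)
    target = med.to_numpy(dtype=float)
    if center:
        profiles = profiles - profiles.mean(axis=1, keepdims=True)
        target = target - target.mean()
    dist = np.sqrt(np.mean((profiles - target) ** 2, axis=1))
    order = sorted(zip(frame.index.astype(str), dist), key=lambda e: (e[1], e[0]))
    return CandidateRanking(entries=order[:k], k=k)


def select_reference(
    measurements: Union[Mapping[str, Sequence[float]], pd.DataFrame],
) -> ReferenceChoice:
    """Choose the candidate with the smallest variation across samples.

    ``measurements`` maps candidate gene id to its per-sample measured
    log quantities (a genes-by-samples DataFrame is also accepted).
    Variation is the sample standard deviation (n−1 denominator).
    Missing values (NaN/None) mark undetermined measurements; a
    candidate with fewer than two determined values cannot be assessed
    and is excluded with a warning.  Ties go to the lexicographically
    smaller gene id.
    """
    if isinstance(measurements, pd.DataFrame):
        measurements = {str(g): measurements.loc[g].tolist() for g in measurements.index}
    if len(measurements) < 2:
        raise ValueError("need at least 2 candidate genes")
    variations: dict[str, float] = {}
    for gene, values in measurements.items():
        arr = np.array([np.nan if v is None else v for v in values], dtype=float)
        determined = arr[np.isfinite(arr)]
        if determined.size < 2:
            warnings.warn(
                f"candidate {gene!r} has fewer than 2 determined values; excluded",
                stacklevel=2,
            )
            continue
        variations[gene] = float(np.std(determined, ddof=1))
    if not variations:
        raise ValueError("no candidate has enough determined measurements")
    chosen = min(variations.items(), key=lambda e: (e[1], e[0]))
    return ReferenceChoice(
        gene_id=chosen[0], variation=chosen[1], per_candidate_variation=variations
    )
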