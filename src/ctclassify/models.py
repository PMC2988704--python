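"""Domain types shared by every pipeline stage.

The central quantity is the cycle threshold (Ct): the PCR cycle at which
a well's fluorescence crosses a fixed detection threshold.  Ct is
inversely proportional to the common logarithm of starting template, so
a linear classifier built on log-normalized relative expression can be
rewritten as an affine function of a weighted sum of ΔCt values
(ΔCt_i(x) = Ct_i(x) − Ct_ref(x)).  The types below carry the objects
that move between stages: raw wells, replicate-aggregated Ct values,
dilution series for efficiency QC, the classifier specification, the
fitted cross-platform calibration, and survival records.

An undetermined Ct (no amplification before the last cycle) is
represented as ``None`` — never coerced to a number — so downstream QC,
not the parser, decides its fate.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

Role = Literal["target", "reference", "negative_control"]
PrognosisGroup = Literal["good", "poor"]
QcFlag = Literal["pass", "warn", "fail"]

__all__ = [
    "AggregatedCt",
    "CalibrationModel",
    "CandidateRanking",
    "ClassifierSpec",
    "CtWell",
    "DilutionSeries",
    "EfficiencyMatchResult",
    "ExpressionMatrix",
    "KMEstimate",
    "HazardRatioResult",
    "LogRankResult",
    "NegativeControlReport",
    "PerGeneStat",
    "PrognosisCall",
    "ReferenceChoice",
    "StandardCurveFit",
    "SurvivalRecord",
]


class CtWell(BaseModel):
    """A single well measurement from a real-time PCR export.

    ``ct is None`` marks an undetermined well (no amplification signal);
    determined values must lie in (0, 40] cycles, the range of a
    standard 40-cycle run.
    """

    model_config = ConfigDict(frozen=True)

    sample_id: str
    gene_id: str
    replicate_index: int = Field(ge=1)
    role: Role = "target"
    ct: Optional[float] = None

    @field_validator("ct")
    @classmethod
    def _ct_in_run_range(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (0.0 < v <= 40.0):
            raise ValueError(f"determined Ct must lie in (0, 40], got {v}")
        return v

    @property
    def undetermined(self) -> bool:
        return self.ct is None


class AggregatedCt(BaseModel):
    """Replicate-aggregated Ct for one (sample, gene) pair."""

    sample_id: str
    gene_id: str
    ct_mean: Optional[float] = None
    ct_range: float = Field(ge=0.0, default=0.0)
    n_replicates: int = Field(ge=1)
    qc_flag: QcFlag = "pass"

    @model_validator(mode="after")
    def _failed_groups_carry_no_mean(self) -> "AggregatedCt":
        if self.qc_flag != "fail" and self.ct_mean is None:
            raise ValueError("non-failing aggregate must carry a ct_mean")
        return self


class DilutionSeries(BaseModel):
    """Ct measured over a serial dilution of template, for one assay.

    ``points`` are (input_amount, ct) pairs; amounts are in nanograms and
    must be strictly monotone so the series is a genuine dilution ladder.
    """

    gene_id: str
    points: list[tuple[float, Optional[float]]]

    @field_validator("points")
    @classmethod
    def _validate_points(cls, pts):
        if len(pts) < 3:
            raise ValueError("a dilution series needs at least 3 points")
        amounts = [a for a, _ in pts]
        if any(a <= 0 for a in amounts):
            raise ValueError("input amounts must be strictly positive")
        diffs = np.diff(amounts)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("input amounts must be strictly monotone")
        return pts

    @property
    def amounts(self) -> np.ndarray:
        return np.array([a for a, _ in self.points], dtype=float)

    @property
    def cts(self) -> np.ndarray:
        return np.array(
            [np.nan if c is None else c for _, c in self.points], dtype=float
        )


class ClassifierSpec(BaseModel):
    """A linear prognosis classifier: weighted sum of log expression.

    ``weights`` maps each diagnostic gene to its fixed coefficient a_i.
    The score of a sample is sum_i a_i * en_i(x) on the original
    platform, or beta1 * sum_i a_i * ΔCt_i(x) + beta0 after conversion.
    ``poor_prognosis_side`` states which side of ``threshold`` is the
    poor-prognosis group; there is deliberately no default because the
    sign convention depends on how the weights were derived.
    """

    name: str
    version: str = "1"
    weights: dict[str, float]
    reference_gene: str
    threshold: float = 0.0
    poor_prognosis_side: Literal["above", "below"]

    @model_validator(mode="after")
    def _check_gene_sets(self) -> "ClassifierSpec":
        if not self.weights:
            raise ValueError("weights must be non-empty")
        if self.reference_gene in self.weights:
            raise ValueError(
                f"reference gene {self.reference_gene!r} must not carry a weight"
            )
        return self

    @property
    def gene_ids(self) -> list[str]:
        return list(self.weights)

    @property
    def n_genes(self) -> int:
        return len(self.weights)


class PerGeneStat(BaseModel):
    """Cross-platform agreement statistics for a single gene.

    ``correlation`` is the Pearson r between original-platform log
    expression and −ΔCt; ``slope``/``intercept`` come from the
    regression of log expression on −ΔCt (so a perfectly efficient,
    noiseless assay gives slope log10(2) ≈ 0.30).
    """

    gene_id: str
    correlation: float = Field(ge=-1.0, le=1.0)
    slope: float
    intercept: float


class CalibrationModel(BaseModel):
    """Fitted affine map from the Ct-based score onto the original scale.

    PC1(x) = beta1 * PC1_rt(x) + beta0.  In theory beta1 = −log10(1+E)
    and beta0 absorbs all control-sample terms, which is why no control
    sample is required once the regression is fitted.
    """

    beta1: float
    beta0: float
    pearson_r: float = Field(ge=-1.0, le=1.0)
    retained_genes: list[str]
    removed_genes: list[str]
    per_gene_stats: list[PerGeneStat] = Field(default_factory=list)
    reference_gene: str
    notes: str = ""

    @model_validator(mode="after")
    def _disjoint_partition(self) -> "CalibrationModel":
        overlap = set(self.retained_genes) & set(self.removed_genes)
        if overlap:
            raise ValueError(f"genes both retained and removed: {sorted(overlap)}")
        return self


class SurvivalRecord(BaseModel):
    """Progression-free survival for one sample.

    ``time`` in months from surgery; ``event`` is True when progression
    was observed, False when follow-up ended without progression
    (censored).
    """

    sample_id: str
    time: float = Field(ge=0.0)
    event: bool
    group_label: Optional[str] = None


class PrognosisCall(BaseModel):
    """Classification of one sample by the converted predictor."""

    sample_id: str
    pc1_rt_score: float
    pc1_score: float
    group: PrognosisGroup


class CandidateRanking(BaseModel):
    """Genes ranked by similarity to the per-sample median profile."""

    entries: list[tuple[str, float]]
    k: int = Field(ge=1)

    @field_validator("entries")
    @classmethod
    def _sorted_nonnegative(cls, entries):
        dists = [d for _, d in entries]
        if any(d < 0 for d in dists):
            raise ValueError("distances must be non-negative")
        if any(b < a for a, b in zip(dists, dists[1:])):
            raise ValueError("entries must be sorted by non-decreasing distance")
        return entries


class ReferenceChoice(BaseModel):
    """The selected reference gene and the variation of every candidate."""

    gene_id: str
    variation: float = Field(ge=0.0)
    per_candidate_variation: dict[str, float]

    @model_validator(mode="after")
    def _chosen_minimises(self) -> "ReferenceChoice":
        if self.per_candidate_variation:
            best = min(self.per_candidate_variation.values())
            if self.variation > best + 1e-12:
                raise ValueError("chosen gene does not minimise variation")
        return self


class StandardCurveFit(BaseModel):
    """Least-squares fit of Ct against log10(input amount).

    The amplification efficiency follows from the slope as
    E = 10^(−1/slope) − 1; perfect doubling gives slope −1/log10(2)
    ≈ −3.32 and E = 1.  Noisy fits can put E outside [0, 1]; such fits
    are reported but flagged via ``efficiency_nominal``.
    """

    gene_id: str
    slope: float
    intercept: float
    efficiency: float
    r_squared: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _efficiency_matches_slope(self) -> "StandardCurveFit":
        expected = 10.0 ** (-1.0 / self.slope) - 1.0
        if not math.isclose(self.efficiency, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError("efficiency inconsistent with slope")
        return self

    @property
    def efficiency_nominal(self) -> bool:
        return 0.0 <= self.efficiency <= 1.0


class EfficiencyMatchResult(BaseModel):
    """Does a target assay amplify as efficiently as the reference assay?

    ``delta_ct_slope`` is the slope of (target Ct − reference Ct) against
    log10(input amount); the assay passes when its absolute value is
    below the criterion (default 0.1 cycles per decade).
    """

    gene_id: str
    delta_ct_slope: float
    criterion: float = Field(gt=0.0, default=0.1)
    passes: bool

    @model_validator(mode="after")
    def _pass_consistent(self) -> "EfficiencyMatchResult":
        if self.passes != (abs(self.delta_ct_slope) < self.criterion):
            raise ValueError("passes flag inconsistent with slope and criterion")
        return self


class NegativeControlReport(BaseModel):
    """Outcome of the negative-control screen on a plate."""

    passed: bool
    min_ct: float
    n_controls: int = Field(ge=0)
    failing_wells: list[CtWell] = Field(default_factory=list)


class KMEstimate(BaseModel):
    """Kaplan-Meier product-limit survival estimate for one group."""

    group_label: Optional[str] = None
    times: list[float]
    survival: list[float]
    ci_low: list[float]
    ci_high: list[float]
    n_at_risk: list[int]

    @model_validator(mode="after")
    def _valid_step_function(self) -> "KMEstimate":
        n = len(self.times)
        if not (len(self.survival) == len(self.ci_low) == len(self.ci_high) == n):
            raise ValueError("times, survival and bands must have equal length")
        s = self.survival
        if n and abs(s[0] - 1.0) > 1e-12:
            raise ValueError("survival must start at 1")
        if any(b > a + 1e-12 for a, b in zip(s, s[1:])):
            raise ValueError("survival must be non-increasing")
        for lo, mid, hi in zip(self.ci_low, s, self.ci_high):
            if lo > mid + 1e-9 or mid > hi + 1e-9:
                raise ValueError("confidence band must bracket the estimate")
        return self


class LogRankResult(BaseModel):
    """Two-group log-rank comparison of survival curves."""

    chi_square: float = Field(ge=0.0)
    p_value: float = Field(gt=0.0, le=1.0)
    groups: tuple[str, str]
    df: int = 1


class HazardRatioResult(BaseModel):
    """Univariate proportional-hazards hazard ratio with Wald inference."""

    hr: float = Field(gt=0.0)
    ci_low: float
    ci_high: float
    p_value: float = Field(gt=0.0, le=1.0)

    @model_validator(mode="after")
    def _ci_brackets_hr(self) -> "HazardRatioResult":
        if not (self.ci_low <= self.hr <= self.ci_high):
            raise ValueError("confidence interval must bracket the hazard ratio")
        return self


class ExpressionMatrix:
    """Log-normalized relative expression, genes as rows, samples as columns.

    Values are common-logarithm (base 10) relative expression levels, the
    scale on which linear classifiers of this kind are defined.  Backed
    by a :class:`pandas.DataFrame`; gene and sample identifiers must be
    unique and every value finite.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if frame.index.has_duplicates:
            dups = frame.index[frame.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if frame.columns.has_duplicates:
            dups = frame.columns[frame.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = frame.to_numpy(dtype=float)  # raises on non-numeric cells
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite expression value at gene {frame.index[r]!r}, "
                f"sample {frame.columns[c]!r}"
            )
        frame = pd.DataFrame(values, index=frame.index.astype(str),
                             columns=frame.columns.astype(str))
        self._frame = frame

    @classmethod
    def from_arrays(cls, gene_ids, sample_ids, values) -> "ExpressionMatrix":
        return cls(pd.DataFrame(np.asarray(values, dtype=float),
                                index=list(gene_ids), columns=list(sample_ids)))

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    @property
    def gene_ids(self) -> list[str]:
        return self._frame.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._frame.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self._frame.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self._frame.shape

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:
        g, s = self.shape
        return f"ExpressionMatrix({g} genes x {s} samples)"
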