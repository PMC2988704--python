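# Methods

## The conversion model

A linear classifier on log-normalized relative expression assigns each
sample x the score PC1(x) = Σᵢ aᵢ·enᵢ(x), with coefficients aᵢ fixed by
a prior learning study. Real-time PCR measures the cycle threshold
Ctᵢ(x), and under the delta-delta Ct model the relative expression of
gene i against a control sample c is

    erᵢ(x) = (1+E)^−(Ctᵢ(x) − Ctᵢ(c)),     0 ≤ E ≤ 1,

where 1+E is the per-cycle amplification factor. Normalizing by a
reference gene and taking common logarithms,

    enᵢ(x) = −log₁₀(1+E)·(Ctᵢ(x) − Ct_ref(x)) + log₁₀(1+E)·(Ctᵢ(c) − Ct_ref(c)).

Substituting into the weighted sum gives PC1(x) = β₁·PC1_rt(x) + β₀
with PC1_rt(x) = Σᵢ aᵢ·ΔCtᵢ(x), β₁ = −log₁₀(1+E), and β₀ collecting
every control-sample term. The implementation never requires E or a
control sample: β₁ and β₀ are estimated by ordinary least squares of
the original-platform scores on the Ct-based scores over samples
measured on both platforms. The assumption that makes a single β₁
meaningful is efficiency matching across assays, which is exactly what
the QC criterion enforces.

Key consequences used as exact test oracles:

* noiseless data with shared efficiency E give β₁ = −log₁₀(1+E) and
  per-gene regression slopes (log expression on −ΔCt) of log₁₀(1+E),
  bounded by log₁₀2 ≈ 0.30 at perfect efficiency;
* β₀ reduces to the reference-gene's weighted baseline term when both
  platforms share a common Ct baseline;
* measurement errors independent across genes shrink by weighted
  averaging, so the composite-score cross-platform correlation exceeds
  every single-gene correlation.

## Stage-by-stage choices

**Reference-gene selection.** Candidates are the genes most similar to
the per-sample median expression pattern. Similarity is root-mean-square
deviation from the median profile after subtracting each profile's own
mean: "similar pattern" is a statement about shape across samples, not
absolute level, and centring makes a constant offset irrelevant. This
centring is this package's design choice; ranking without centring is
available via `rank_candidates(..., center=False)`. The final choice
among candidates minimizes the sample standard deviation (n−1
denominator) of re-measured log quantities; ties break lexicographically
so results are order-independent. A single reference gene is used — a
multi-gene composite would average in additional measurement variance
here, where candidates were already pre-selected for stability.

**Assay QC.** Standard curves regress Ct on log₁₀(input amount) over a
serial dilution (default seven 10-fold steps spanning 20 ng–20 fg, six
decades); efficiency is E = 10^(−1/slope) − 1 and values outside [0, 1]
are reported but flagged rather than clipped, since noisy fits can
exceed perfect doubling. Efficiency matching is tested directly on the
quantity that matters for ΔCt: the slope of (target Ct − reference Ct)
against log₁₀(input), with pass criterion |slope| < 0.1 cycles per
decade. Replicate wells aggregate by mean; undetermined replicates are
dropped, never imputed, and a fully undetermined group fails QC. The
replicate-range warn threshold of 0.5 cycles is deliberately generous
against a typical replicate sd below 0.1 cycles. Negative controls must
be undetermined or at background level (Ct ≥ 37, versus 16–31 cycles
for genuine template).

**Gene filtering.** "No cross-platform correlation" is operationalized
as a numeric threshold on the per-gene Pearson r, default r_min = 0.2
(configurable). On the bundled 30-gene glioma panel statistics this
threshold cleanly separates the three uncorrelated genes (r ≤ 0.11)
from the retained ones (r ≥ 0.43). Per-gene regressions orient log
expression on −ΔCt so that well-behaved genes have positive slopes with
the log₁₀(1+E) theoretical value.

**Classification.** PC1 scores at or beyond the threshold on the
classifier's declared poor-prognosis side are called poor; a score
exactly at the threshold goes to the poor side, the conservative choice
for a prognosis screen. The side is a mandatory field of the classifier
specification because the sign convention of principal-component
weights is arbitrary.

**Survival validation.** Kaplan–Meier estimates carry pointwise 95%
bands from Greenwood's variance on the log(−log) scale (the
"exponential Greenwood" construction, which keeps bands inside [0, 1]).
The log-rank test is the standard observed-minus-expected chi-square
with hypergeometric variance, df = 1, two-sided p. The hazard ratio
comes from a univariate Cox partial-likelihood fit with the Efron tie
correction — survival recorded in whole months is heavily tied — and
Wald 95% CI and p-value. All of this is delegated to `lifelines`; the
test suite checks it against hand-coded risk-table enumerations.

## The cohort simulator

`simulate_cohort` draws, in fixed order from one seeded generator:

* latent prognosis score z ~ N(0, 1) per sample;
* per-gene baseline μᵢ ~ N(0, 0.5) and loading bᵢ = ±|N(0.3, 0.1)|
  (random sign), so true log₁₀ expression is μᵢ + bᵢ·z;
* classifier weights aᵢ = bᵢ + N(0, 0.05) — what a first principal
  component fitted on the noisy expression matrix would approximately
  recover; the unprinted real weight vector is not available, so
  weights are simulated and exported in the ground truth;
* platform A observes truth + N(0, 0.15) log₁₀ units per gene;
* platform B observes Ct = 25 − truth/log₁₀(1+E) + N(0, 0.5) cycles per
  (sample, gene), replicated in triplicate with additional N(0, 0.053)
  per well — 0.053 makes the mean absolute difference between replicate
  wells 2σ/√π ≈ 0.06 cycles, the scale seen on a well-run instrument;
* the reference gene has loading 0 (constant true expression);
* progression-free survival is exponential with log-hazard 0.6·z around
  a baseline hazard of 0.087/month (median ≈ 8 months at z = 0), under
  independent exponential censoring (rate 0.04/month, ≈ 30% censored),
  recorded in whole months;
* negative-control wells are undetermined by default, with a config
  switch to inject contamination for QC testing;
* a noiseless dilution ladder per assay (noise optional).

With shared efficiency these defaults put single-gene cross-platform
correlations in the 0.6–0.9 range while the composite score correlates
near 0.99, and leave the OLS estimate of β₁ with |bias| < 0.02 at
n = 100 — the regimes the acceptance tests probe. The default test
problem sizes (100 samples, 27 genes, 20-seed suites) keep the whole
suite fast while leaving those properties comfortably resolved.

What the simulator does **not** emulate: correlated per-gene errors
(e.g. shared plate effects beyond the reference subtraction), probe
cross-hybridization or splice-variant mismatches between platforms
(the real mechanism suspected behind uncorrelated genes), RNA-quality
covariates, non-proportional hazards, and any actual tumour biology.
Passing tests therefore demonstrate the correctness of the algebra,
estimators and decision rules under the stated generative model — not
clinical validity of any particular gene panel.

## Numerical notes and edge cases

* Undetermined Ct is a typed missing value end to end; it is never
  coerced to 40 or any number, and scoring refuses samples with missing
  weighted genes rather than imputing.
* All regressions are `scipy.stats.linregress` (two-variable OLS);
  calibration requires ≥ 3 pairs and nonzero regressor variance.
* Pearson r values are clipped into [−1, 1] to absorb last-ulp
  round-off before validation.
* Distance and variation ties in reference-gene selection break
  lexicographically; classification ties at the threshold go to poor.
* File round-trips are exact: floats serialize at full double precision
  and TSV parsing uses round-trip float conversion.
* The efficiency-match comparison requires identical dilution ladders
  (relative tolerance 1e−9); it does not interpolate across grids.

## Limitations

* The calibration is a single affine map; platform differences that are
  gene-specific and non-linear are only handled by removing the
  offending genes.
* Survival validation covers a two-group comparison with a univariate
  hazard ratio; no multivariate adjustment, competing risks or
  time-varying effects.
* Reference-gene selection implements the median-pattern/minimal-sd
  criterion only; pairwise-stability algorithms (geNorm/NormFinder
  style) are out of scope.
* Classifier weights are consumed as input; deriving them (e.g. by
  principal-component analysis) is a prior study's task, not this
  package's.
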