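# ctclassify

Convert a linear gene-expression prognosis classifier into a
real-time-PCR classifier based on the delta-delta Ct method.

Gene-expression profiling (microarrays, two-colour-style relative
quantification) is a discovery tool; real-time PCR is what clinical labs
actually run. A linear classifier learned on profiling data,

```
PC1(x) = Σᵢ aᵢ · enᵢ(x)
```

(a weighted sum of log-normalized expression values `enᵢ(x)` with fixed
coefficients `aᵢ`), can be re-expressed in cycle thresholds. Because Ct
is inversely proportional to the common log of starting template,
`enᵢ(x) = −log₁₀(1+E)·ΔCtᵢ(x) + const` with amplification efficiency
`E` and `ΔCtᵢ(x) = Ctᵢ(x) − Ct_ref(x)`, so

```
PC1(x) = β₁ · PC1_rt(x) + β₀ ,     PC1_rt(x) = Σᵢ aᵢ · ΔCtᵢ(x)
```

where in theory `β₁ = −log₁₀(1+E)` and `β₀` absorbs all control-sample
terms. Fitting `β₁, β₀` by least squares on samples measured on both
platforms calibrates the Ct-based score onto the original scale — no
control sample needed at scoring time. Independent per-gene measurement
errors largely cancel in the weighted sum, so the composite score
transfers between platforms far better than any individual gene; the
conversion is therefore done at the score level, never gene by gene.

The package implements the complete workflow for this conversion:

- **`ctclassify.refgene`** — reference-gene selection: rank genes by
  similarity to the per-sample median expression pattern, then pick the
  re-measured candidate with the smallest standard deviation.
- **`ctclassify.qc`** — assay QC: standard-curve efficiency fits
  (`E = 10^(−1/slope) − 1`), the efficiency-match criterion
  (|slope of ΔCt vs log₁₀ input| < 0.1), replicate aggregation, and
  negative-control screening (quiet means undetermined or Ct ≥ 37).
- **`ctclassify.conversion`** — the ΔCt algebra, `PC1_rt` scoring,
  calibration regression, per-gene cross-platform statistics, the
  correlation-based gene filter (default r ≥ 0.2), and threshold
  classification into good/poor prognosis groups.
- **`ctclassify.survival`** — validation of the called groups against
  progression-free survival: Kaplan–Meier curves with 95% bands,
  log-rank test, Cox hazard ratio (via `lifelines`).
- **`ctclassify.simulate`** — a ground-truthed synthetic two-platform
  cohort generator (latent prognosis score, per-gene loadings, platform
  noise, replicated Ct wells, dilution ladders, survival outcomes), so
  every stage is testable end to end.
- **`ctclassify.data`** — the published per-gene cross-platform
  parameters of the 30-gene glioma prognosis panel, the canonical
  worked example for the gene filter.

## Worked example

```python
import ctclassify as ctc

cohort = ctc.simulate_cohort(ctc.SimulationConfig(seed=7))   # 100 samples, 27 genes
agg = ctc.aggregate_replicates(cohort.ct_wells)
dct = ctc.delta_ct(agg, cohort.config.reference_gene)
cal = ctc.fit_conversion(cohort.expression, dct, cohort.classifier_spec)
print(f"beta1 = {cal.beta1:.4f}   (theory: -log10(2) = -0.3010)")
print(f"score correlation r = {cal.pearson_r:.3f}")

calls = ctc.score_and_classify(dct, cohort.classifier_spec, cal)
groups = {c.sample_id: c.group for c in calls}
records = [r.model_copy(update={"group_label": groups[r.sample_id]})
           for r in cohort.survival]
lr = ctc.logrank_test(records, "good", "poor")
hr = ctc.cox_hr(records, exposed_group="poor")
print(f"log-rank chi2 = {lr.chi_square:.2f}, p = {lr.p_value:.2e}")
print(f"HR = {hr.hr:.2f} (95% CI {hr.ci_low:.2f}-{hr.ci_high:.2f})")
```

prints

```
beta1 = -0.2931   (theory: -log10(2) = -0.3010)
score correlation r = -0.990
log-rank chi2 = 8.23, p = 4.13e-03
HR = 2.16 (95% CI 1.26-3.69)
```

The fitted `β₁` sits near its theoretical value at perfect efficiency
(slightly attenuated by Ct noise on the regressor); the composite-score
correlation |r| = 0.99 far exceeds the best single-gene cross-platform
correlation in the same cohort (0.85) — the error-cancellation property
that justifies converting the score rather than individual genes. The
poor-prognosis group progresses about twice as fast as the good group.

And the gene filter on the published 30-gene panel statistics:

```python
from ctclassify.data import load_glioma30_stats
retained, removed = ctc.filter_genes(load_glioma30_stats())
# 27 retained; removed == ['VMP1', 'TNC', 'RHOC']
```

## Command line

The same workflow is exposed as `ctclassify` subcommands — `simulate`,
`refgene`, `qc`, `calibrate`, `score`, `validate`, and `run` (the whole
pipeline from one JSON config):

```bash
ctclassify simulate --seed 7 --out cohort/
ctclassify calibrate --expression cohort/expression.tsv --ct cohort/ct_export.tsv \
    --classifier cohort/classifier.json --out cal.json
ctclassify score --ct cohort/ct_export.tsv --classifier cohort/classifier.json \
    --calibration cal.json --out calls.csv
ctclassify validate --calls calls.csv --survival cohort/survival.csv --out validation.json
```

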