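"""Core conversion algebra: ΔCt, scores, calibration, per-gene filtering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctclassify import (
    calibrate,
    delta_ct,
    filter_genes,
    log_normalized_expression,
    pc1_rt,
    per_gene_stats,
    relative_expression,
    score_and_classify,
)
from ctclassify.conversion import MissingGeneError, MissingReferenceError
from ctclassify.models import AggregatedCt, CalibrationModel, ClassifierSpec, PerGeneStat


def agg(sample, gene, ct, flag="pass"):
    return AggregatedCt(
        sample_id=sample, gene_id=gene,
        ct_mean=None if flag == "fail" else ct,
        n_replicates=3, qc_flag=flag,
    )


def spec_for(weights, **kw):
    kw.setdefault("poor_prognosis_side", "above")
    return ClassifierSpec(name="t", weights=weights, reference_gene="REF", **kw)


class TestDeltaCt:
    def test_equal_cts_give_zero(self):
        dct = delta_ct([agg("S1", "Gi", 25.0), agg("S1", "REF", 25.0)], "REF")
        assert dct.loc["Gi", "S1"] == 0.0

    def test_simple_subtraction(self):
        dct = delta_ct([agg("S1", "Gi", 26.5), agg("S1", "REF", 24.0)], "REF")
        assert dct.loc["Gi", "S1"] == pytest.approx(2.5)

    def test_full_plate_matches_elementwise_oracle(self, rng):
        genes = [f"G{i:02d}" for i in range(30)]
        samples = ["S1", "S2", "S3"]
        cts = {(g, s): float(rng.uniform(18, 32)) for g in genes for s in samples}
        refs = {s: float(rng.uniform(20, 24)) for s in samples}
        aggs = [agg(s, g, cts[(g, s)]) for g in genes for s in samples]
        aggs += [agg(s, "REF", refs[s]) for s in samples]
        dct = delta_ct(aggs, "REF")
        for g in genes:
            for s in samples:
                assert dct.loc[g, s] == pytest.approx(cts[(g, s)] - refs[s])
        assert "REF" not in dct.index

    def test_missing_reference_names_the_sample(self):
        aggs = [agg("S1", "Gi", 25.0), agg("S1", "REF", 24.0), agg("S2", "Gi", 25.0)]
        with pytest.raises(MissingReferenceError, match="S2"):
            delta_ct(aggs, "REF")

    def test_failed_reference_counts_as_missing(self):
        aggs = [agg("S1", "Gi", 25.0), agg("S1", "REF", None, flag="fail")]
        with pytest.raises(MissingReferenceError, match="S1"):
            delta_ct(aggs, "REF")

    def test_failed_target_becomes_nan_not_error(self):
        dct = delta_ct(
            [agg("S1", "Gi", None, flag="fail"), agg("S1", "REF", 24.0)], "REF"
        )
        assert np.isnan(dct.loc["Gi", "S1"])


class TestRelativeExpression:
    @pytest.mark.parametrize("efficiency", [0.0, 0.5, 1.0])
    def test_equal_cts_give_unity(self, efficiency):
        assert relative_expression(25.0, 25.0, efficiency) == 1.0

    def test_one_perfect_cycle_doubles(self):
        assert relative_expression(24.0, 25.0, 1.0) == pytest.approx(2.0)

    def test_direct_power_evaluation(self):
        assert relative_expression(28.0, 25.0, 0.9) == pytest.approx(1.9**-3)

    @pytest.mark.parametrize("efficiency", [-0.1, 1.5])
    def test_efficiency_outside_unit_interval_rejected(self, efficiency):
        with pytest.raises(ValueError, match="efficiency"):
            relative_expression(25.0, 25.0, efficiency)


class TestLogNormalizedExpression:
    def test_equal_delta_cts_give_zero(self):
        assert log_normalized_expression(1.7, 1.7, 0.8) == 0.0

    def test_one_cycle_at_perfect_efficiency(self):
        assert log_normalized_expression(-1.0, 0.0, 1.0) == pytest.approx(
            math.log10(2.0)
        )

    @given(
        ct_x=st.floats(15, 35), ct_c=st.floats(15, 35),
        ct_rx=st.floats(15, 35), ct_rc=st.floats(15, 35),
        efficiency=st.floats(0.5, 1.0),
    )
    def test_consistent_with_relative_expression_ratio(
        self, ct_x, ct_c, ct_rx, ct_rc, efficiency
    ):
        via_ratio = math.log10(
            relative_expression(ct_x, ct_c, efficiency)
            / relative_expression(ct_rx, ct_rc, efficiency)
        )
        direct = log_normalized_expression(ct_x - ct_rx, ct_c - ct_rc, efficiency)
        assert direct == pytest.approx(via_ratio, abs=1e-9)


class TestPc1Rt:
    def test_zero_weights_score_zero(self):
        dct = pd.DataFrame([[2.5, -1.0]], index=["G1"], columns=["S1", "S2"])
        scores = pc1_rt(dct, spec_for({"G1": 0.0}))
        assert list(scores) == [0.0, 0.0]

    def test_single_gene_unit_weight(self):
        dct = pd.DataFrame([[2.5]], index=["G1"], columns=["S1"])
        assert pc1_rt(dct, spec_for({"G1": 1.0}))["S1"] == pytest.approx(2.5)

    def test_matches_loop_accumulation_oracle(self, rng):
        genes = [f"G{i}" for i in range(27)]
        weights = {g: float(rng.normal()) for g in genes}
        dct = pd.DataFrame(rng.normal(size=(27, 9)), index=genes,
                           columns=[f"S{j}" for j in range(9)])
        scores = pc1_rt(dct, spec_for(weights))
        for s in dct.columns:
            total = 0.0
            for g in genes:
                total += weights[g] * dct.loc[g, s]
            assert scores[s] == pytest.approx(total, rel=1e-12)

    def test_missing_gene_is_an_error_not_a_drop(self):
        dct = pd.DataFrame([[1.0]], index=["G1"], columns=["S1"])
        with pytest.raises(MissingGeneError, match="G2"):
            pc1_rt(dct, spec_for({"G1": 1.0, "G2": 1.0}))

    def test_unmeasured_cell_is_an_error_naming_gene_and_sample(self):
        dct = pd.DataFrame([[1.0, np.nan]], index=["G1"], columns=["S1", "S2"])
        with pytest.raises(MissingGeneError, match="G1/S2"):
            pc1_rt(dct, spec_for({"G1": 1.0}))

    def test_per_gene_constant_shift_adds_a_constant(self, rng):
        genes = [f"G{i}" for i in range(5)]
        weights = {g: float(rng.normal()) for g in genes}
        dct = pd.DataFrame(rng.normal(size=(5, 7)), index=genes,
                           columns=[f"S{j}" for j in range(7)])
        shift = pd.Series(rng.normal(size=5), index=genes)
        base = pc1_rt(dct, spec_for(weights))
        moved = pc1_rt(dct.add(shift, axis=0), spec_for(weights))
        expected_const = sum(weights[g] * shift[g] for g in genes)
        assert np.allclose(moved - base, expected_const)


class TestCalibrate:
    def test_noiseless_line_recovered_exactly(self):
        x = pd.Series([0.0, 1.0, 2.0, 3.0], index=list("abcd"))
        y = -math.log10(2.0) * x + 0.0
        beta1, beta0, r = calibrate(y, x)
        assert beta1 == pytest.approx(-math.log10(2.0), abs=1e-12)
        assert beta0 == pytest.approx(0.0, abs=1e-12)
        assert abs(r) == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_normal_equations(self, rng):
        x = pd.Series(rng.normal(size=40), index=[f"s{i}" for i in range(40)])
        y = -0.37 * x - 0.002 + pd.Series(rng.normal(0, 0.3, 40), index=x.index)
        beta1, beta0, r = calibrate(y, x)
        xa, ya = x.to_numpy(), y.to_numpy()
        sxx = ((xa - xa.mean()) ** 2).sum()
        sxy = ((xa - xa.mean()) * (ya - ya.mean())).sum()
        assert beta1 == pytest.approx(sxy / sxx, rel=1e-10)
        assert beta0 == pytest.approx(ya.mean() - (sxy / sxx) * xa.mean(), rel=1e-10)
        syy = ((ya - ya.mean()) ** 2).sum()
        assert r == pytest.approx(sxy / math.sqrt(sxx * syy), rel=1e-10)

    def test_too_few_pairs_rejected(self):
        x = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match=">= 3"):
            calibrate(x, x)

    def test_zero_variance_scores_rejected(self):
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        x = pd.Series([5.0, 5.0, 5.0], index=list("abc"))
        with pytest.raises(ValueError, match="variance"):
            calibrate(y, x)

    def test_differing_sample_sets_rejected(self):
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        x = pd.Series([1.0, 2.0, 3.0], index=list("abd"))
        with pytest.raises(ValueError, match="sample sets"):
            calibrate(y, x)


class TestPerGeneStats:
    def test_exact_affine_relation_recovered(self):
        samples = [f"s{i}" for i in range(6)]
        dct = pd.DataFrame([np.linspace(-2, 3, 6)], index=["G1"], columns=samples)
        expr = pd.DataFrame(0.30 * (-dct.loc["G1"].to_numpy()) + 0.5,
                            index=samples, columns=["G1"]).T
        (stat,) = per_gene_stats(expr, dct)
        assert stat.correlation == pytest.approx(1.0)
        assert stat.slope == pytest.approx(0.30)
        assert stat.intercept == pytest.approx(0.5)

    def test_matches_textbook_formula_oracles(self, rng):
        samples = [f"s{i}" for i in range(25)]
        genes = ["Ga", "Gb", "Gc"]
        dct = pd.DataFrame(rng.normal(size=(3, 25)), index=genes, columns=samples)
        expr = pd.DataFrame(rng.normal(size=(3, 25)), index=genes, columns=samples)
        stats = per_gene_stats(expr, dct)
        for stat in stats:
            x = -dct.loc[stat.gene_id].to_numpy()
            y = expr.loc[stat.gene_id].to_numpy()
            sxx = ((x - x.mean()) ** 2).mean()
            sxy = ((x - x.mean()) * (y - y.mean())).mean()
            syy = ((y - y.mean()) ** 2).mean()
            assert stat.correlation == pytest.approx(sxy / math.sqrt(sxx * syy), rel=1e-9)
            assert stat.slope == pytest.approx(sxy / sxx, rel=1e-9)
            assert stat.intercept == pytest.approx(y.mean() - (sxy / sxx) * x.mean(),
                                                   rel=1e-9)

    def test_gene_with_too_few_shared_samples_excluded(self):
        samples = ["s1", "s2", "s3", "s4"]
        dct = pd.DataFrame(
            [[1.0, 2.0, np.nan, np.nan], [1.0, 2.0, 3.0, 4.0]],
            index=["SPARSE", "FULL"], columns=samples,
        )
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [0.5, 1.0, 1.5, 2.0]],
            index=["SPARSE", "FULL"], columns=samples,
        )
        with pytest.warns(UserWarning, match="SPARSE"):
            stats = per_gene_stats(expr, dct)
        assert [s.gene_id for s in stats] == ["FULL"]

    def test_correlations_invariant_under_per_gene_ct_shift(self, rng):
        samples = [f"s{i}" for i in range(15)]
        genes = ["Ga", "Gb"]
        dct = pd.DataFrame(rng.normal(size=(2, 15)), index=genes, columns=samples)
        expr = pd.DataFrame(rng.normal(size=(2, 15)), index=genes, columns=samples)
        base = per_gene_stats(expr, dct)
        shifted = per_gene_stats(expr, dct.add(pd.Series([3.0, -1.5], index=genes),
                                               axis=0))
        for b, s in zip(base, shifted):
            assert s.correlation == pytest.approx(b.correlation, rel=1e-9)
            assert s.slope == pytest.approx(b.slope, rel=1e-9)


class TestFilterGenes:
    def stats(self, corrs):
        return [
            PerGeneStat(gene_id=g, correlation=c, slope=0.3, intercept=0.0)
            for g, c in corrs.items()
        ]

    def test_zero_threshold_keeps_nonnegative(self):
        retained, removed = filter_genes(
            self.stats({"A": 0.0, "B": 0.5, "C": -0.1}), r_min=0.0
        )
        assert retained == ["A", "B"] and removed == ["C"]

    def test_partition_matches_brute_force_scan(self, rng):
        corrs = {f"G{i}": float(rng.uniform(-1, 1)) for i in range(50)}
        retained, removed = filter_genes(self.stats(corrs), r_min=0.2)
        assert retained == [g for g, c in corrs.items() if c >= 0.2]
        assert removed == [g for g, c in corrs.items() if c < 0.2]

    @given(r_lo=st.floats(-1, 1), r_hi=st.floats(-1, 1))
    def test_removal_is_monotone_in_threshold(self, r_lo, r_hi):
        r_lo, r_hi = min(r_lo, r_hi), max(r_lo, r_hi)
        corrs = {f"G{i}": c for i, c in enumerate(np.linspace(-0.9, 0.95, 20))}
        _, removed_lo = filter_genes(self.stats(corrs), r_min=r_lo)
        _, removed_hi = filter_genes(self.stats(corrs), r_min=r_hi)
        assert set(removed_lo) <= set(removed_hi)

    def test_empty_stats_rejected(self):
        with pytest.raises(ValueError):
            filter_genes([])


class TestScoreAndClassify:
    def cal(self, retained, beta1=1.0, beta0=0.0):
        return CalibrationModel(
            beta1=beta1, beta0=beta0, pearson_r=0.9,
            retained_genes=retained, removed_genes=[], reference_gene="REF",
        )

    def test_sign_determines_group_with_identity_map(self):
        dct = pd.DataFrame([[0.5, -0.5]], index=["G1"], columns=["S1", "S2"])
        calls = score_and_classify(dct, spec_for({"G1": 1.0}), self.cal(["G1"]))
        assert {c.sample_id: c.group for c in calls} == {"S1": "poor", "S2": "good"}

    def test_score_exactly_at_threshold_is_poor(self):
        dct = pd.DataFrame([[0.0]], index=["G1"], columns=["S1"])
        (call,) = score_and_classify(dct, spec_for({"G1": 1.0}), self.cal(["G1"]))
        assert call.group == "poor"

    def test_poor_side_below_flips_calls(self):
        dct = pd.DataFrame([[0.5, -0.5]], index=["G1"], columns=["S1", "S2"])
        spec = spec_for({"G1": 1.0}, poor_prognosis_side="below")
        calls = score_and_classify(dct, spec, self.cal(["G1"]))
        assert {c.sample_id: c.group for c in calls} == {"S1": "good", "S2": "poor"}

    def test_matches_per_sample_affine_oracle(self, rng):
        genes = [f"G{i}" for i in range(8)]
        weights = {g: float(rng.normal()) for g in genes}
        dct = pd.DataFrame(rng.normal(size=(8, 12)), index=genes,
                           columns=[f"S{j}" for j in range(12)])
        beta1, beta0 = -0.37, -0.002
        spec = spec_for(weights)
        calls = score_and_classify(dct, spec, self.cal(genes, beta1, beta0))
        for call in calls:
            rt = sum(weights[g] * dct.loc[g, call.sample_id] for g in genes)
            score = beta1 * rt + beta0
            assert call.pc1_rt_score == pytest.approx(rt, rel=1e-12)
            assert call.pc1_score == pytest.approx(score, rel=1e-12)
            assert call.group == ("poor" if score >= 0.0 else "good")

    def test_call_invariant_under_other_sample_reordering(self, rng):
        genes = ["G1", "G2"]
        dct = pd.DataFrame(rng.normal(size=(2, 6)), index=genes,
                           columns=[f"S{j}" for j in range(6)])
        spec = spec_for({g: 1.0 for g in genes})
        cal = self.cal(genes)
        base = {c.sample_id: c for c in score_and_classify(dct, spec, cal)}
        shuffled = dct[dct.columns[::-1]]
        for c in score_and_classify(shuffled, spec, cal):
            assert c == base[c.sample_id]

    def test_scoring_uses_only_retained_genes(self):
        dct = pd.DataFrame([[1.0], [100.0]], index=["G1", "G2"], columns=["S1"])
        spec = spec_for({"G1": 1.0, "G2": 1.0})
        cal = CalibrationModel(
            beta1=1.0, beta0=0.0, pearson_r=0.9,
            retained_genes=["G1"], removed_genes=["G2"], reference_gene="REF",
        )
        (call,) = score_and_classify(dct, spec, cal)
        assert call.pc1_rt_score == pytest.approx(1.0)
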