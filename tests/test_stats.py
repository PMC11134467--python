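import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asecross.counting import GeneAlleleTable, SampleInfo, aggregate_gene_counts
from asecross.stats import (
    ClassifyThresholds,
    GeneTestResult,
    NotTestableError,
    bh_adjust,
    classify_gene,
    fit_quasibinomial_intercept,
    run_ase_tests,
)
from asecross.stats import test_all_genes as fit_gene_axes
from conftest import bh_brute_force, irls_quasibinomial


class TestQuasiBinomialFit:
    def test_exact_null_gives_p_one(self):
        fit = fit_quasibinomial_intercept([10, 10, 10, 10], [20, 20, 20, 20])
        assert fit.p_hat == 0.5
        assert fit.beta == 0.0
        assert fit.p_value == 1.0

    def test_worked_example_matches_irls_oracle(self):
        s, n = [30, 25, 28, 27], [40, 40, 40, 40]
        fit = fit_quasibinomial_intercept(s, n)
        assert fit.p_hat == pytest.approx(110 / 160)
        assert fit.beta == pytest.approx(np.log((110 / 160) / (50 / 160)), abs=1e-10)
        oracle = irls_quasibinomial(s, n)
        assert fit.beta == pytest.approx(oracle["beta"], abs=1e-8)
        assert fit.se == pytest.approx(oracle["se"], abs=1e-8)
        assert fit.phi == pytest.approx(oracle["phi"], abs=1e-8)
        assert fit.p_value == pytest.approx(oracle["p_value"], abs=1e-8)

    def test_single_sample_not_testable(self):
        with pytest.raises(NotTestableError):
            fit_quasibinomial_intercept([5], [10])

    def test_zero_total_samples_excluded_from_df(self):
        fit = fit_quasibinomial_intercept([5, 7, 0], [10, 10, 0])
        assert fit.df_resid == 1

    def test_degenerate_proportion_uses_continuity(self):
        fit = fit_quasibinomial_intercept([10, 12, 9], [10, 12, 9])
        assert fit.p_hat == 1.0
        assert np.isfinite(fit.beta) and np.isfinite(fit.p_value)
        assert fit.beta == pytest.approx(np.log(31.5 / 0.5))

    def test_agrees_with_statsmodels_pearson_scale(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        for _ in range(20):
            n = rng.integers(5, 200, size=rng.integers(3, 9))
            s = rng.binomial(n, rng.uniform(0.15, 0.85))
            if s.sum() == 0 or s.sum() == n.sum():
                continue
            fit = fit_quasibinomial_intercept(s, n)
            res = sm.GLM(
                s / n, np.ones(len(n)),
                family=sm.families.Binomial(), var_weights=n,
            ).fit(scale="X2")
            assert fit.beta == pytest.approx(res.params[0], abs=1e-8)
            assert fit.se == pytest.approx(res.bse[0], abs=1e-8)
            assert fit.phi == pytest.approx(res.scale, abs=1e-8)

    def test_closed_form_matches_irls_on_random_instances(self):
        """The full oracle sweep: 100 random instances, agreement to 1e-8."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 100:
            n = rng.integers(1, 300, size=rng.integers(2, 12))
            p_true = rng.uniform(0.05, 0.95)
            s = rng.binomial(n, p_true)
            if s.sum() == 0 or s.sum() == n.sum():
                continue
            fit = fit_quasibinomial_intercept(s, n)
            oracle = irls_quasibinomial(s, n)
            assert fit.beta == pytest.approx(oracle["beta"], abs=1e-8)
            assert fit.se == pytest.approx(oracle["se"], abs=1e-8)
            assert fit.phi == pytest.approx(oracle["phi"], abs=1e-8)
            assert fit.p_value == pytest.approx(oracle["p_value"], abs=1e-8)
            checked += 1


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.3] * 5), [0.3] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            p = rng.random(rng.integers(1, 51))
            np.testing.assert_allclose(bh_adjust(p), bh_brute_force(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=30))
    @settings(derandomize=True, max_examples=100)
    def test_adjustment_preserves_order(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


def result(**kw):
    base = dict(
        gene_id="g", p_parent=0.001, p_ecotype=0.5,
        prop_maternal_hb=0.5, prop_maternal_bh=0.5,
        prop_head_hb=0.5, prop_head_bh=0.5,
        max_sample_maternal=10, max_sample_paternal=10,
        max_sample_head=10, max_sample_body=10,
        q_parent=1.0, q_ecotype=1.0,
    )
    base.update(kw)
    return GeneTestResult(**base)


class TestClassification:
    def test_significant_and_high_in_both_directions_is_maternal(self):
        r = result(q_parent=0.01, prop_maternal_hb=0.7, prop_maternal_bh=0.7)
        assert classify_gene(r) == "maternal_biased"

    def test_one_direction_below_cutoff_stays_biparental(self):
        r = result(q_parent=0.01, prop_maternal_hb=0.7, prop_maternal_bh=0.55)
        assert classify_gene(r) == "biparental"

    def test_silenced_paternal_allele_is_limited(self):
        r = result(
            q_parent=0.01, prop_maternal_hb=1.0, prop_maternal_bh=1.0,
            max_sample_paternal=0,
        )
        assert classify_gene(r) == "maternal_limited"

    def test_nonsignificant_extreme_proportion_stays_biparental(self):
        r = result(q_parent=0.2, prop_maternal_hb=0.9, prop_maternal_bh=0.9)
        assert classify_gene(r) == "biparental"

    def test_head_bias_requires_both_directions(self):
        r = result(q_ecotype=0.01, prop_head_hb=0.8, prop_head_bh=0.8)
        assert classify_gene(r) == "head_biased"
        r2 = result(q_ecotype=0.01, prop_head_hb=0.8, prop_head_bh=0.5)
        assert classify_gene(r2) == "biparental"

    def test_paternal_mirror(self):
        r = result(q_parent=0.01, prop_maternal_hb=0.2, prop_maternal_bh=0.3)
        assert classify_gene(r) == "paternal_biased"

    def test_limited_tolerance_option(self):
        r = result(
            q_parent=0.01, prop_maternal_hb=0.95, prop_maternal_bh=0.95,
            max_sample_paternal=1,
        )
        assert classify_gene(r) == "maternal_biased"
        assert classify_gene(r, ClassifyThresholds(limited_tol=1)) == "maternal_limited"

    @given(
        q_par=st.floats(0, 1), q_eco=st.floats(0, 1),
        pm_hb=st.floats(0, 1), pm_bh=st.floats(0, 1),
        cutoff=st.floats(0.51, 0.99),
    )
    @settings(derandomize=True, max_examples=300)
    def test_parent_and_ecotype_axes_mutually_exclusive(
        self, q_par, q_eco, pm_hb, pm_bh, cutoff
    ):
        """prop_head is tied to prop_maternal per direction, so with
        cutoff > 0.5 a gene can never satisfy both axis rules at once."""
        r = result(
            q_parent=q_par, q_ecotype=q_eco,
            prop_maternal_hb=pm_hb, prop_maternal_bh=pm_bh,
            prop_head_hb=pm_hb, prop_head_bh=1 - pm_bh,
        )
        th = ClassifyThresholds(prop_cutoff=cutoff)
        cat = classify_gene(r, th)
        parent_rule = (min(pm_hb, pm_bh) > cutoff) or (max(pm_hb, pm_bh) < 1 - cutoff)
        ecotype_rule = (min(pm_hb, 1 - pm_bh) > cutoff) or (
            max(pm_hb, 1 - pm_bh) < 1 - cutoff
        )
        assert not (parent_rule and ecotype_rule)
        if cat.startswith(("maternal", "paternal")):
            assert parent_rule and q_par < th.alpha
        if cat.startswith(("head", "body")):
            assert ecotype_rule and q_eco < th.alpha


def make_table(rows, samples):
    return aggregate_gene_counts(pd.DataFrame(rows), samples)


class TestTestAllGenes:
    def build(self, samples, maternal_prop=0.5, depth=40, n_genes=4, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g in range(n_genes):
            for s in samples:
                m = rng.binomial(depth, maternal_prop)
                head = m if s.cross == "HB" else depth - m
                rows.append(
                    {"sample_id": s.sample_id, "chrom": "c", "pos": g * 10 + 1,
                     "head": head, "body": depth - head, "other": 0,
                     "gene_id": f"g{g}"}
                )
        return make_table(rows, samples)

    def test_cross_relabel_swaps_parent_axis_only(self, samples_5_4):
        table = self.build(samples_5_4, maternal_prop=0.7, seed=3)
        flipped = [
            SampleInfo(s.sample_id, "BH" if s.cross == "HB" else "HB")
            for s in samples_5_4
        ]
        t2 = GeneAlleleTable(
            gene_counts=table.gene_counts.drop(columns=["cross", "maternal", "paternal"]),
            snp_counts=table.snp_counts,
            samples=table.samples,
        )
        table_flipped = make_table(
            table.snp_counts.to_dict("records"), flipped
        )
        r1 = {r.gene_id: r for r in fit_gene_axes(table)}
        r2 = {r.gene_id: r for r in fit_gene_axes(table_flipped)}
        for g in r1:
            # ecotype axis untouched by relabelling
            assert r1[g].p_ecotype == pytest.approx(r2[g].p_ecotype, abs=1e-12)
            assert r1[g].prop_head_hb == pytest.approx(r2[g].prop_head_bh, abs=1e-12)
            # parent-axis proportions swap direction labels and flip
            assert r1[g].prop_maternal_hb == pytest.approx(
                1 - r2[g].prop_maternal_bh, abs=1e-12
            )

    def test_fully_maternal_gene_handled_via_continuity(self, samples_5_4):
        rows = [
            {"sample_id": s.sample_id, "chrom": "c", "pos": 1,
             "head": 30 if s.cross == "HB" else 0,
             "body": 0 if s.cross == "HB" else 30,
             "other": 0, "gene_id": "g0"}
            for s in samples_5_4
        ]
        res = run_ase_tests(make_table(rows, samples_5_4))
        row = res.iloc[0]
        assert row["prop_maternal_hb"] == 1.0 and row["prop_maternal_bh"] == 1.0
        assert np.isfinite(row["p_parent"])
        assert row["category"] == "maternal_limited"

    def test_head_limited_gene_called_on_ecotype_axis(self, samples_5_4):
        rows = [
            {"sample_id": s.sample_id, "chrom": "c", "pos": 1,
             "head": 40, "body": 0, "other": 0, "gene_id": "g0"}
            for s in samples_5_4
        ]
        res = run_ase_tests(make_table(rows, samples_5_4))
        assert res.iloc[0]["category"] == "head_limited"

    def test_prop_head_identity_with_prop_maternal(self, samples_5_4):
        table = self.build(samples_5_4, maternal_prop=0.6, seed=11)
        for r in fit_gene_axes(table):
            assert r.prop_head_hb == pytest.approx(r.prop_maternal_hb, abs=1e-12)
            assert r.prop_head_bh == pytest.approx(1 - r.prop_maternal_bh, abs=1e-12)
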