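import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from polyrisk import panel
from polyrisk.association import (
    TwoByTwo,
    allele_table,
    assoc_test,
    bonferroni,
    counts_allele_table,
    cv_auc_compare,
    dominant_recessive,
    lr_interaction_test,
    odds_ratio_ci,
    power_two_proportions,
)
from polyrisk.io import GenotypeCounts
from polyrisk.simulate import SimulationConfig, simulate_case_control
from conftest import make_dataset

counts = st.integers(1, 500)


class TestOddsRatio:
    def test_symmetric_table_is_null(self):
        r = odds_ratio_ci(TwoByTwo(50, 50, 50, 50))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.ci_low < 1 < r.ci_high

    @given(counts, counts, counts, counts)
    @settings(max_examples=100, deadline=None)
    def test_matches_cross_product_and_woolf_oracle(self, a, b, c, d):
        r = odds_ratio_ci(TwoByTwo(a, b, c, d))
        orr = (a * d) / (b * c)
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        assert r.odds_ratio == pytest.approx(orr)
        assert r.ci_low == pytest.approx(orr * np.exp(-1.959964 * se), rel=1e-5)
        assert r.ci_high == pytest.approx(orr * np.exp(1.959964 * se), rel=1e-5)
        assert r.ci_low <= r.odds_ratio <= r.ci_high

    @given(counts, counts, counts, counts)
    @settings(max_examples=50, deadline=None)
    def test_group_swap_inverts(self, a, b, c, d):
        r = odds_ratio_ci(TwoByTwo(a, b, c, d))
        s = odds_ratio_ci(TwoByTwo(c, d, a, b))
        assert s.odds_ratio == pytest.approx(1 / r.odds_ratio)
        assert s.ci_low == pytest.approx(1 / r.ci_high)
        assert s.ci_high == pytest.approx(1 / r.ci_low)

    def test_zero_cell_undefined_without_correction(self):
        # recessive table with no minor homozygotes among controls
        r = odds_ratio_ci(TwoByTwo(2, 787, 0, 531))
        assert not r.defined and np.isnan(r.odds_ratio)

    def test_haldane_correction_defines_zero_cell(self):
        r = odds_ratio_ci(TwoByTwo(2, 787, 0, 531), correction="haldane")
        assert r.defined
        expected = (2.5 * 531.5) / (787.5 * 0.5)
        assert r.odds_ratio == pytest.approx(expected)

    def test_empty_margin_rejected_without_correction(self):
        with pytest.raises(ValueError, match="margin"):
            odds_ratio_ci(TwoByTwo(0, 10, 0, 10))

    def test_woolf_interval_coverage(self, rng):
        # simulate 2x2 tables with known OR; ~95% of intervals cover it
        true_or = 1.6
        p0 = 0.2
        odds1 = p0 / (1 - p0) * true_or
        p1 = odds1 / (1 + odds1)
        n = 400
        covered = 0
        reps = 400
        for _ in range(reps):
            a = rng.binomial(n, p1)
            c = rng.binomial(n, p0)
            t = TwoByTwo(a, n - a, c, n - c)
            r = odds_ratio_ci(t, correction="haldane")
            covered += r.ci_low <= true_or <= r.ci_high
        assert covered / reps == pytest.approx(0.95, abs=0.03)


class TestAssocTest:
    def test_uniform_table_p_one(self):
        assert assoc_test(TwoByTwo(10, 10, 10, 10)) == pytest.approx(1.0)

    def test_chi2_equals_two_proportion_ztest(self, rng):
        from statsmodels.stats.proportion import proportions_ztest

        for _ in range(20):
            a, b, c, d = rng.integers(20, 200, size=4)
            p_chi = assoc_test(TwoByTwo(a, b, c, d))
            _, p_z = proportions_ztest([a, c], [a + b, c + d])
            assert p_chi == pytest.approx(p_z, rel=1e-8)

    def test_fisher_used_for_sparse_2x2(self):
        t = TwoByTwo(1, 40, 6, 35)  # expected count < 5 in one cell
        assert assoc_test(t) == pytest.approx(stats.fisher_exact(t.as_array())[1])

    def test_2x3_genotype_table(self):
        g = np.array([[575, 192, 22], [428, 94, 9]], float)
        expected = stats.chi2_contingency(g, correction=False)[1]
        assert assoc_test(g) == pytest.approx(expected)
        assert assoc_test(g) == pytest.approx(0.0051, abs=5e-4)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            assoc_test(np.array([[0, 0, 0], [1, 2, 3]], float))


class TestStudyPanelValues:
    """Frozen published statistics recomputed from the embedded counts."""

    def test_allele_table_from_cohort(self):
        ds = panel.matched_cohort(seed=0)
        t = allele_table(ds, "rs11574311")
        assert (t.a, t.b, t.c, t.d) == (236, 1342, 112, 950)

    @pytest.mark.parametrize(
        "snp,expected",
        [
            ("rs11574311", (1.49, 1.17, 1.90)),
            ("rs2725383", (1.27, 1.00, 1.62)),
            ("rs2304277", (0.89, 0.76, 1.04)),
        ],
    )
    def test_published_allelic_or_ci(self, snp, expected):
        control, case = panel.GENOTYPE_COUNTS[snp]
        r = odds_ratio_ci(counts_allele_table(case, control))
        assert (round(r.odds_ratio, 2), round(r.ci_low, 2), round(r.ci_high, 2)) == expected

    def test_dominant_recessive_published(self):
        ds = panel.matched_cohort(seed=0)
        dom, _ = dominant_recessive(ds, "rs11574311")
        assert round(dom.odds_ratio, 2) == 1.55
        _, rec = dominant_recessive(ds, "rs4733220")
        assert round(rec.odds_ratio, 2) == 0.73

    def test_no_control_minor_homozygote_recessive_undefined(self):
        ds = panel.matched_cohort(seed=0)
        _, rec = dominant_recessive(ds, "rs7183308")
        assert not rec.defined

    def test_dominant_or_one_when_all_het(self):
        ds = make_dataset([[1]] * 40, [0, 1] * 20)
        dom, _ = dominant_recessive(ds, "snp01", correction="haldane")
        assert dom.odds_ratio == pytest.approx(1.0)


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.003, 18, 0.054), (0.5, 10, 1.0), (0.01, 3, 0.03)]
    )
    def test_values(self, p, m, expected):
        assert bonferroni(p, m) == pytest.approx(expected)

    def test_requires_positive_m(self):
        with pytest.raises(ValueError):
            bonferroni(0.01, 0)


class TestPower:
    def test_study_scale_power_above_85_percent(self):
        assert power_two_proportions(1062, 1578, 0.105, 1.5, 0.05) > 0.85

    def test_null_or_gives_alpha(self):
        assert power_two_proportions(500, 500, 0.2, 1.0, 0.05) == pytest.approx(
            0.05, abs=1e-10
        )

    def test_monotone_in_n_and_effect(self):
        grid_n = [200, 500, 1500, 5000]
        powers = [power_two_proportions(n, n, 0.105, 1.5) for n in grid_n]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        grid_or = [1.1, 1.3, 1.6, 2.2]
        powers = [power_two_proportions(800, 800, 0.105, o) for o in grid_or]
        assert all(a < b for a, b in zip(powers, powers[1:]))
        # symmetric in ln OR: protective effects equally detectable
        assert power_two_proportions(800, 800, 0.3, 0.5) == pytest.approx(
            power_two_proportions(800, 800, 0.3, 2.0), abs=0.02
        )


class TestInteractionLogistic:
    def test_single_snp_rejected(self):
        ds = make_dataset([[0], [1]], [0, 1])
        with pytest.raises(ValueError):
            lr_interaction_test(ds, ["snp01"])

    def test_constructed_product_effect_detected(self, rng):
        n = 1200
        g1 = rng.binomial(2, 0.4, n)
        g2 = rng.binomial(2, 0.4, n)
        d1, d2 = (g1 >= 1).astype(float), (g2 >= 1).astype(float)
        logit = -1.0 + 0.1 * d1 + 0.1 * d2 + 1.8 * d1 * d2
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        ds = make_dataset(np.column_stack([g1, g2]), y.astype(int))
        res = lr_interaction_test(ds, ["snp01", "snp02"])
        assert res.converged
        assert res.df == 1
        assert res.p_value < 1e-3

    def test_null_independent_snps_not_significant(self, rng):
        # modest calibration check: null p-values not systematically small
        ps = []
        for seed in range(25):
            r = np.random.default_rng(seed)
            n = 400
            g = r.binomial(2, 0.3, size=(n, 2))
            y = r.integers(0, 2, n)
            ds = make_dataset(g, y)
            res = lr_interaction_test(ds, ["snp01", "snp02"])
            if res.converged:
                ps.append(res.p_value)
        ps = np.array(ps)
        assert (ps < 0.05).mean() < 0.25
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestCvAuc:
    def test_separable_data_test_auc_near_one(self):
        geno = np.array([[0, 0]] * 100 + [[2, 2]] * 100)
        y = np.array([0] * 100 + [1] * 100)
        ds = make_dataset(geno, y)
        out = cv_auc_compare(ds, ["snp01", "snp02"], folds=5, seed=0)
        assert out["test_auc"] > 0.99

    def test_label_permuted_near_half(self, rng):
        n = 1000
        g = rng.binomial(2, 0.3, size=(n, 3))
        y = rng.permutation(np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)])
        ds = make_dataset(g, y)
        out = cv_auc_compare(ds, ds.snp_ids, folds=10, seed=1)
        assert out["test_auc"] == pytest.approx(0.5, abs=0.05)

    def test_training_auc_optimism(self, rng):
        # train AUC >= test AUC in expectation over repeated datasets
        diffs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 300
            g = r.binomial(2, 0.3, size=(n, 4))
            y = r.integers(0, 2, n)
            ds = make_dataset(g, y)
            diffs.append(cv_auc_compare(ds, ds.snp_ids, folds=5, seed=seed)["difference"])
        assert np.mean(diffs) > 0
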