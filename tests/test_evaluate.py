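"""Stratified OR tables, Hosmer–Lemeshow, DeLong AUC, sensitivity/specificity."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.special import expit

from prstrat.evaluate import (
    auc_delong,
    decile_bins,
    hosmer_lemeshow,
    integrated_model,
    sens_spec,
    stratified_or_table,
)
from prstrat.pipeline import PUBLISHED_DECILE_CASES, PUBLISHED_DECILE_CONTROLS
from prstrat.prs import compute_prs
from prstrat.synthetic import SimulationSpec, default_covariate_spec, simulate_cohort


def bins_from_counts(controls, cases):
    bins, y = [], []
    for d, (nc, ncase) in enumerate(zip(controls, cases), start=1):
        bins += [d] * (nc + ncase)
        y += [0] * nc + [1] * ncase
    return np.array(bins), np.array(y)


class TestStratifiedOrTable:
    def test_top_decile_or_matches_published_value(self):
        bins, y = bins_from_counts(PUBLISHED_DECILE_CONTROLS, PUBLISHED_DECILE_CASES)
        table = stratified_or_table(bins, y, ref_bin=5)
        assert round(table[9].odds_ratio, 2) == 4.58
        assert table[4].is_reference and table[4].odds_ratio == 1.0

    def test_identical_case_control_ratio_gives_unit_or(self):
        bins, y = bins_from_counts([50, 80], [25, 40])
        table = stratified_or_table(bins, y, ref_bin=1)
        assert table[1].odds_ratio == pytest.approx(1.0)

    def test_hand_arithmetic_cross_check(self):
        # (62 controls, 122 cases) vs reference (94 controls, 74 cases)
        bins, y = bins_from_counts([94, 62], [74, 122])
        table = stratified_or_table(bins, y, ref_bin=1)
        assert table[1].odds_ratio == pytest.approx(122 * 94 / (62 * 74), abs=1e-12)
        assert round(table[1].odds_ratio, 1) == 2.5

    def test_percentages_use_status_group_denominators(self):
        bins, y = bins_from_counts(PUBLISHED_DECILE_CONTROLS, PUBLISHED_DECILE_CASES)
        table = stratified_or_table(bins, y, ref_bin=5)
        assert sum(r.pct_controls for r in table) == pytest.approx(100.0)
        assert sum(r.pct_cases for r in table) == pytest.approx(100.0)
        assert table[9].pct_cases == pytest.approx(100 * 137 / 880)

    def test_bin_empty_of_one_status_flagged(self):
        bins, y = bins_from_counts([10, 5, 0], [10, 0, 5])
        table = stratified_or_table(bins, y, ref_bin=1)
        assert {r.flag for r in table[1:]} == {"empty-status"}
        assert table[1].odds_ratio is None

    def test_reference_bin_must_contain_both_statuses(self):
        bins, y = bins_from_counts([10, 0], [10, 5])
        with pytest.raises(ValueError, match="reference"):
            stratified_or_table(bins, y, ref_bin=2)


class TestHosmerLemeshow:
    def test_constant_correct_probability_gives_zero_chi2(self):
        y = np.array([0, 1] * 10)
        p_hat = np.full(20, 0.5)
        res = hosmer_lemeshow(p_hat, y, n_groups=2)  # ties collapse to one group
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_published_chi2_df_pair_reproduces_printed_p(self):
        assert round(float(stats.chi2.sf(11.77, 8)), 3) == 0.162

    def test_toy_example_matches_hand_expansion(self):
        p_hat = np.array([0.2, 0.3, 0.4, 0.6, 0.7, 0.8])
        y = np.array([0.0, 1, 0, 1, 0, 1])
        res = hosmer_lemeshow(p_hat, y, n_groups=2)
        # group 1: O=1, E=0.9, n=3; group 2: O=2, E=2.1, n=3
        expected = ((1 - 0.9) ** 2 / 0.9 + (2 - 2.1) ** 2 / 2.1
                    + (2 - 2.1) ** 2 / 2.1 + (1 - 0.9) ** 2 / 0.9)
        assert res.chi2 == pytest.approx(expected, abs=1e-12)
        assert res.df == 0
        np.testing.assert_allclose(res.table["expected"].sum(), p_hat.sum(), atol=1e-6)

    def test_ties_never_straddle_groups(self):
        p_hat = np.array([0.2] * 6 + [0.8] * 4)
        y = np.array([0] * 6 + [1] * 4)
        res = hosmer_lemeshow(p_hat, y, n_groups=5)
        assert len(res.table) == 2
        assert res.table["n"].tolist() == [6, 4]

    def test_probabilities_on_boundary_rejected(self):
        with pytest.raises(ValueError):
            hosmer_lemeshow(np.array([0.0, 0.5, 0.5, 0.5]), np.array([0, 1, 0, 1]), 2)


def brute_force_auc(scores, y):
    cases = scores[y == 1]
    controls = scores[y == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))


class TestAucDelong:
    def test_perfect_separation(self):
        res = auc_delong(np.array([3.0, 4, 1, 2]), np.array([1, 1, 0, 0]))
        assert res.auc == 1.0
        assert res.ci_high <= 1.0

    def test_uninformative_scores(self):
        res = auc_delong(np.ones(10), np.array([1] * 5 + [0] * 5))
        assert res.auc == 0.5

    def test_four_observation_pair_enumeration(self):
        scores = np.array([0.9, 0.4, 0.6, 0.2])
        y = np.array([1, 1, 0, 0])
        res = auc_delong(scores, y)
        assert res.auc == pytest.approx(brute_force_auc(scores, y)) == 0.75

    @given(
        n=st.integers(5, 60),
        frac=st.floats(0.2, 0.8),
        levels=st.integers(2, 8),
        seed=st.integers(0, 1000),
    )
    def test_equals_brute_force_pair_counting(self, n, frac, levels, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, levels, n).astype(float)  # force ties
        y = (rng.random(n) < frac).astype(int)
        if y.sum() in (0, n):
            y[0], y[-1] = 0, 1
        res = auc_delong(scores, y)
        assert res.auc == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_interval_brackets_the_estimate(self, rng):
        scores = rng.normal(size=200) + np.repeat([0.0, 0.8], 100)
        y = np.repeat([0, 1], 100)
        res = auc_delong(scores, y)
        assert 0.0 <= res.ci_low <= res.auc <= res.ci_high <= 1.0
        assert res.se > 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_delong(np.arange(4.0), np.ones(4))


class TestSensSpec:
    def test_perfect_classifier(self):
        sens, spec = sens_spec(np.array([0.9, 0.9, 0.1, 0.1]), np.array([1, 1, 0, 0]))
        assert (sens, spec) == (1.0, 1.0)

    def test_constant_probability_above_threshold(self):
        sens, spec = sens_spec(np.full(6, 0.6), np.array([1, 1, 1, 0, 0, 0]))
        assert (sens, spec) == (1.0, 0.0)

    def test_direct_count(self):
        sens, spec = sens_spec(np.array([0.7, 0.3, 0.6, 0.1]), np.array([1, 1, 0, 0]))
        assert (sens, spec) == (0.5, 0.5)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            sens_spec(np.array([0.4, 0.6]), np.array([1, 1]))


@pytest.fixture(scope="module")
def fitted(weights):
    cohort, genotypes, truth = simulate_cohort(SimulationSpec(seed=33))
    scores = np.array([r.score for r in compute_prs(genotypes, weights)])
    return cohort, integrated_model(cohort, scores), truth


class TestIntegratedModel:
    def test_decile_structure_and_conservation(self, fitted):
        cohort, result, _ = fitted
        table = result.decile_table
        assert len(table) == 10
        assert sum(r.is_reference for r in table) == 1
        assert sum(r.pct_controls for r in table) == pytest.approx(100.0)
        assert sum(r.pct_cases for r in table) == pytest.approx(100.0)
        assert sum(r.n_cases + r.n_controls for r in table) == len(cohort)

    def test_decile_bins_are_balanced_partition(self, fitted):
        _, result, _ = fitted
        bins = decile_bins(result.p_hat, 10)
        counts = np.bincount(bins, minlength=11)[1:]
        assert counts.sum() == len(result.p_hat)
        assert counts.max() - counts.min() <= 1

    def test_metrics_are_coherent(self, fitted):
        _, result, _ = fitted
        assert 0.5 < result.discrimination.auc < 1.0
        assert result.calibration.chi2 >= 0
        assert 0 < result.sensitivity < 1 and 0 < result.specificity < 1
        assert result.fit.converged

    def test_risk_gradient_rises_across_deciles(self, fitted):
        _, result, _ = fitted
        ors = [r.odds_ratio for r in result.decile_table if not r.is_reference]
        assert ors[0] < 1.0 < ors[-1]

    def test_null_model_out_of_fold_auc_near_half(self, weights):
        """Under an all-null generating model the model has no discrimination:
        the cross-validated AUC averages 0.5 (the apparent AUC would sit above
        0.5 by the overfitting optimism of a 14-term fit)."""
        from prstrat.evaluate import cross_validated_auc

        cov = {k: dataclasses.replace(v, beta=0.0)
               for k, v in default_covariate_spec().items()}
        aucs = []
        for seed in range(20):
            spec = SimulationSpec(n_cases=1000, n_controls=1000,
                                  snp_betas=[0.0] * 15, covariate_spec=cov,
                                  intercept=0.0, prevalence=None, seed=600 + seed)
            cohort, genotypes, _ = simulate_cohort(spec)
            scores = np.array([r.score for r in compute_prs(genotypes, weights)])
            res = cross_validated_auc(cohort, scores, n_folds=5, seed=seed)
            aucs.append(res.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.02

    def test_apparent_auc_exceeds_out_of_fold_auc_under_null(self, weights):
        cov = {k: dataclasses.replace(v, beta=0.0)
               for k, v in default_covariate_spec().items()}
        spec = SimulationSpec(n_cases=1000, n_controls=1000, snp_betas=[0.0] * 15,
                              covariate_spec=cov, intercept=0.0, prevalence=None,
                              seed=700)
        cohort, genotypes, _ = simulate_cohort(spec)
        scores = np.array([r.score for r in compute_prs(genotypes, weights)])
        from prstrat.evaluate import cross_validated_auc

        apparent = integrated_model(cohort, scores).discrimination.auc
        held_out = cross_validated_auc(cohort, scores, seed=1).auc
        assert apparent > held_out
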