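"""Cox interaction engine: likelihood, Newton fits, tests, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coxfilter import (
    DataError,
    ExpressionMatrix,
    SimulationConfig,
    W_C1,
    W_C2,
    adjust_pvalues,
    classify_gene,
    fit_cox_gene,
    generate_matched_cohort,
    lrt_linear_test,
    partial_loglik,
    screen_genes,
    screen_genes_matched,
    wald_linear_test,
)
from coxfilter.screening import CoxGeneFit, newton_cox

from .oracles import bh_oracle, brute_partial_loglik, grid_search_cox


def _design(d):
    return np.column_stack([d["i_c2"], d["x"], d["i_c2"] * d["x"]])


class TestPartialLoglik:
    def test_zero_beta_equals_log_risk_set_sizes(self, toy6):
        ll, _, _ = partial_loglik(np.zeros(3), _design(toy6),
                                  toy6["time"], toy6["event"])
        sizes = [np.sum(toy6["time"] >= t) for t in toy6["time"]]
        assert np.isclose(ll, -np.sum(np.log(sizes)))

    def test_single_subject_single_event(self):
        ll, grad, _ = partial_loglik([0.3, -0.2, 0.1],
                                     np.array([[1.0, 2.0, 2.0]]),
                                     [5.0], [1])
        assert ll == pytest.approx(0.0)
        assert np.allclose(grad, 0.0)

    def test_matches_brute_force_oracle(self, toy6):
        beta = np.array([0.1, 0.2, -0.1])
        Z = _design(toy6)
        ll, _, _ = partial_loglik(beta, Z, toy6["time"], toy6["event"])
        assert np.isclose(
            ll, brute_partial_loglik(beta, Z, toy6["time"], toy6["event"]),
            atol=1e-12)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_tied_data_matches_oracle(self, ties):
        rng = np.random.default_rng(7)
        n = 12
        Z = rng.normal(size=(n, 3))
        time = np.array([1, 1, 1, 2, 2, 3, 3, 3, 4, 5, 5, 6], dtype=float)
        event = np.array([1, 1, 0, 1, 1, 1, 1, 1, 0, 1, 1, 1])
        beta = np.array([0.4, -0.3, 0.2])
        ll, _, _ = partial_loglik(beta, Z, time, event, ties)
        assert np.isclose(ll, brute_partial_loglik(beta, Z, time, event, ties),
                          atol=1e-12)

    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_gradient_information_match_finite_differences(self, toy8, ties):
        Z = _design(toy8)
        beta = np.array([0.15, -0.25, 0.35])
        ll, grad, info = partial_loglik(beta, Z, toy8["time"],
                                        toy8["event"], ties)
        h = 1e-6
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            lp = partial_loglik(beta + e, Z, toy8["time"], toy8["event"], ties)[0]
            lm = partial_loglik(beta - e, Z, toy8["time"], toy8["event"], ties)[0]
            assert np.isclose(grad[j], (lp - lm) / (2 * h), rtol=1e-5)
            gp = partial_loglik(beta + e, Z, toy8["time"], toy8["event"], ties)[1]
            gm = partial_loglik(beta - e, Z, toy8["time"], toy8["event"], ties)[1]
            assert np.allclose(-info[:, j], (gp - gm) / (2 * h), rtol=1e-4,
                               atol=1e-7)

    def test_efron_equals_breslow_without_ties(self, toy8):
        Z = _design(toy8)
        beta = np.array([0.5, -0.7, 0.2])
        le = partial_loglik(beta, Z, toy8["time"], toy8["event"], "efron")
        lb = partial_loglik(beta, Z, toy8["time"], toy8["event"], "breslow")
        assert abs(le[0] - lb[0]) < 1e-10
        assert np.allclose(le[1], lb[1], atol=1e-10)
        assert np.allclose(le[2], lb[2], atol=1e-10)

    def test_no_events_error(self, toy6):
        with pytest.raises(DataError, match="no events"):
            partial_loglik(np.zeros(3), _design(toy6), toy6["time"],
                           np.zeros(6, dtype=int))

    def test_loglik_nonpositive_probability_form(self, toy8):
        # product of probabilities <= 1 under both ties methods
        for ties in ("efron", "breslow"):
            ll, _, _ = partial_loglik([0.1, 0.3, -0.2], _design(toy8),
                                      toy8["time"], toy8["event"], ties)
            assert ll <= 0


class TestFitCoxGene:
    def test_matches_grid_search_oracle(self, toy8):
        fit = fit_cox_gene(toy8["x"], toy8["i_c2"], toy8["time"],
                           toy8["event"], gene_id="toy8")
        assert fit.converged
        beta_grid, ll_grid = grid_search_cox(_design(toy8), toy8["time"],
                                             toy8["event"])
        assert np.all(np.abs(fit.beta - beta_grid) < 2e-2)
        assert abs(fit.loglik - ll_grid) < 1e-4

    def test_matches_lifelines(self, toy8):
        lifelines = pytest.importorskip("lifelines")
        fit = fit_cox_gene(toy8["x"], toy8["i_c2"], toy8["time"],
                           toy8["event"])
        df = pd.DataFrame({"i2": toy8["i_c2"], "x": toy8["x"],
                           "ix": toy8["i_c2"] * toy8["x"],
                           "t": toy8["time"], "e": toy8["event"]})
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        assert np.allclose(fit.beta, cph.params_.values, atol=1e-4)
        assert np.isclose(fit.loglik, cph.log_likelihood_, atol=1e-6)

    def test_likelihood_ascent(self, toy8):
        # step-halving guarantees a non-decreasing loglik path; the optimum
        # must beat the null model
        Z = _design(toy8)
        ll0 = partial_loglik(np.zeros(3), Z, toy8["time"], toy8["event"])[0]
        fit = fit_cox_gene(toy8["x"], toy8["i_c2"], toy8["time"], toy8["event"])
        assert fit.loglik >= ll0

    def test_constant_expression_unfit(self, toy8):
        fit = fit_cox_gene(np.ones(8), toy8["i_c2"], toy8["time"],
                           toy8["event"])
        assert not fit.converged
        assert "degenerate covariate" in fit.message

    def test_stratum_constant_expression_unfit(self, toy8):
        x = np.where(toy8["i_c2"] == 1, 2.0, 1.0)
        fit = fit_cox_gene(x, toy8["i_c2"], toy8["time"], toy8["event"])
        assert not fit.converged
        assert "interaction inestimable" in fit.message

    def test_no_events_unfit(self, toy8):
        fit = fit_cox_gene(toy8["x"], toy8["i_c2"], toy8["time"],
                           np.zeros(8, dtype=int))
        assert not fit.converged and fit.message == "no events"

    def test_monotone_likelihood_flagged(self):
        # c2 events ordered exactly by expression: interaction diverges
        x = np.array([0.0, 0.1, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        i_c2 = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        time = np.array([7.0, 8.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        fit = fit_cox_gene(x, i_c2, time, np.ones(8, dtype=int))
        assert not fit.converged
        assert "monotone" in fit.message

    def test_label_swap_symmetry(self, toy8):
        fit = fit_cox_gene(toy8["x"], toy8["i_c2"], toy8["time"],
                           toy8["event"])
        swapped = fit_cox_gene(toy8["x"], 1 - toy8["i_c2"], toy8["time"],
                               toy8["event"])
        # swapping c1<->c2 maps b2 -> b2+b3 (and b3 -> -b3)
        assert np.isclose(swapped.beta[1], fit.beta[1] + fit.beta[2],
                          atol=1e-6)
        _, p1 = wald_linear_test(fit, W_C1)
        _, p2s = wald_linear_test(swapped, W_C2)
        assert np.isclose(p1, p2s, atol=1e-6)
        _, p2 = wald_linear_test(fit, W_C2)
        _, p1s = wald_linear_test(swapped, W_C1)
        assert np.isclose(p2, p1s, atol=1e-6)


class TestWaldTest:
    def _fit(self, beta, cov):
        return CoxGeneFit("g", np.asarray(beta, float),
                          np.asarray(cov, float), -1.0, 5, True, 3, "ok")

    def test_zero_contrast_gives_p_one(self):
        z, p = wald_linear_test(self._fit([0.5, 0.0, 0.3], np.eye(3)), W_C1)
        assert z == 0.0 and p == 1.0

    def test_exact_cancellation(self):
        z, p = wald_linear_test(self._fit([0.2, 1.0, -1.0], np.eye(3)), W_C2)
        assert z == 0.0 and p == 1.0

    def test_hand_computed_variance(self):
        cov = np.array([[0.1, 0.0, 0.0],
                        [0.0, 0.04, -0.01],
                        [0.0, -0.01, 0.09]])
        z, p = wald_linear_test(self._fit([0.0, 0.5, 0.3], cov), W_C2)
        expected_z = 0.8 / np.sqrt(0.04 + 0.09 + 2 * -0.01)
        assert np.isclose(z, expected_z)
        assert np.isclose(p, 2 * stats.norm.sf(expected_z))

    def test_nonpositive_variance_error(self):
        with pytest.raises(DataError, match="non-positive variance"):
            wald_linear_test(self._fit([0, 1, 0], np.zeros((3, 3))), W_C1)

    def test_unconverged_fit_rejected(self, toy8):
        fit = fit_cox_gene(np.ones(8), toy8["i_c2"], toy8["time"],
                           toy8["event"])
        with pytest.raises(DataError, match="converge"):
            wald_linear_test(fit, W_C1)

    def test_lrt_agrees_with_wald_at_moderate_n(self):
        cfg = SimulationConfig(n_c1=100, n_c2=100, n_genes=1, frac_null=0.0,
                               frac_c1_only=1.0, frac_c2_only=0.0,
                               frac_shared=0.0, beta2_effect=0.5, seed=3)
        matrix, subtype, times, events, _ = generate_matched_cohort(cfg)
        i_c2 = (subtype == "c2").astype(float)
        fit = fit_cox_gene(matrix.values[0], i_c2, times[0], events[0])
        z, _ = wald_linear_test(fit, W_C1)
        chi2, _ = lrt_linear_test(matrix.values[0], i_c2, times[0],
                                  events[0], W_C1)
        assert np.isclose(chi2, z ** 2, rtol=0.2)


class TestAdjustPvalues:
    def test_bh_textbook_example(self):
        assert np.allclose(adjust_pvalues([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.37])[0] == pytest.approx(0.37)

    def test_all_equal_unchanged(self):
        assert np.allclose(adjust_pvalues([0.2, 0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_independent_bh_oracle(self, pvals):
        adj = adjust_pvalues(pvals)
        assert np.allclose(adj, bh_oracle(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all((0 <= adj) & (adj <= 1))


class TestClassifyGene:
    @pytest.mark.parametrize("a1,a2,expected", [
        (0.01, 0.50, "c1_specific"),
        (0.50, 0.01, "c2_specific"),
        (0.01, 0.01, "shared"),
        (0.50, 0.50, "none"),
        (0.05, 0.05, "none"),  # threshold is strict
    ])
    def test_labels(self, a1, a2, expected):
        assert classify_gene(a1, a2, 0.05) == expected


class TestScreenGenes:
    def test_alpha_zero_empty_sets(self, aligned_cohort):
        matrix, clinical = aligned_cohort
        res = screen_genes(matrix, clinical, alpha=0.0)
        assert res.set_c1 == set() and res.set_c2 == set()
        assert (res.table.loc[res.table["converged"], "label"] == "none").all()

    def test_unfit_gene_excluded_from_adjustment(self, aligned_cohort):
        matrix, clinical = aligned_cohort
        values = matrix.values.copy()
        values[2] = 1.0  # constant gene
        m2 = ExpressionMatrix(matrix.feature_ids, matrix.sample_ids,
                              values, "log2p1")
        res = screen_genes(m2, clinical)
        row = res.table[res.table["gene_id"] == "G2"].iloc[0]
        assert row["label"] == "unfit" and not row["converged"]
        assert np.isnan(row["padj_c1"])
        others = res.table[res.table["gene_id"] != "G2"]
        assert others["converged"].all()

    def test_misaligned_inputs_rejected(self, aligned_cohort):
        matrix, clinical = aligned_cohort
        with pytest.raises(DataError, match="not aligned"):
            screen_genes(matrix, clinical.iloc[::-1].reset_index(drop=True))

    def test_raw_scale_rejected(self, aligned_cohort):
        matrix, clinical = aligned_cohort
        raw = ExpressionMatrix(matrix.feature_ids, matrix.sample_ids,
                               np.abs(matrix.values), "raw")
        with pytest.raises(DataError, match="log2"):
            screen_genes(raw, clinical)

    def test_planted_gene_detected_small(self):
        # one strong c1-only gene among nulls: lands in set_c1, not set_c2
        cfg = SimulationConfig(
            n_genes=40, frac_null=0.975, frac_c1_only=0.025,
            frac_c2_only=0.0, frac_shared=0.0, beta2_effect=2.0, seed=12,
        )
        matrix, subtype, times, events, truths = generate_matched_cohort(cfg)
        res = screen_genes_matched(matrix, subtype, times, events)
        planted = [t.gene_id for t in truths if t.class_label == "c1_only"]
        assert len(planted) == 1
        assert planted[0] in res.set_c1
        assert planted[0] not in res.set_c2

    def test_pooled_adjustment_flag(self, aligned_cohort):
        matrix, clinical = aligned_cohort
        sep = screen_genes(matrix, clinical, adjust_family="separate")
        pooled = screen_genes(matrix, clinical, adjust_family="pooled")
        # unadjusted p identical; adjusted may differ
        assert np.allclose(sep.table["p_c1"], pooled.table["p_c1"])
        assert (pooled.table["padj_c1"] >= sep.table["p_c1"] - 1e-15).all()

    def test_overlap_is_intersection(self, aligned_cohort):
        matrix, clinical = aligned_cohort
        res = screen_genes(matrix, clinical, alpha=0.9)
        assert res.overlap == res.set_c1 & res.set_c2
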