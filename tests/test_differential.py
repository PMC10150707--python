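"""Paired and moderated t-statistics, fold changes, FDR, volcano, summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hydroxyscan.diff import (
    EBPrior,
    bh_fdr,
    classify_volcano,
    fit_eb_prior,
    log2_fold_change,
    moderated_paired_t,
    moderated_t,
    paired_t,
    summarize_direction,
    trigamma_inverse,
    unpaired_t,
)

PAIRS4 = [("a1", "b1"), ("a2", "b2"), ("a3", "b3"), ("a4", "b4")]


def values_from_diffs(diffs: np.ndarray) -> pd.DataFrame:
    """Value matrix whose paired differences (B - A) equal ``diffs`` exactly."""
    n_sites, n_pairs = diffs.shape
    cols = {}
    for j in range(n_pairs):
        cols[f"a{j + 1}"] = np.zeros(n_sites)
        cols[f"b{j + 1}"] = diffs[:, j]
    return pd.DataFrame(cols)


class TestPairedT:
    def test_textbook_formula_oracle(self):
        d = np.array([[0.5, -0.2, 0.3, 0.1]])
        res = paired_t(values_from_diffs(d), PAIRS4)
        mean, sd, n = d.mean(), d.std(ddof=1), 4
        t_expected = mean / (sd / math.sqrt(n))
        p_expected = 2 * stats.t.sf(abs(t_expected), n - 1)
        assert abs(res["t"].iloc[0] - t_expected) < 1e-12
        assert abs(res["p_value"].iloc[0] - p_expected) < 1e-12
        assert res["df"].iloc[0] == 3

    def test_agrees_with_scipy_ttest_rel(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(200, 4))
        vals = values_from_diffs(d)
        res = paired_t(vals, PAIRS4)
        b = vals[[p[1] for p in PAIRS4]].to_numpy()
        a = vals[[p[0] for p in PAIRS4]].to_numpy()
        ref = stats.ttest_rel(b, a, axis=1)
        np.testing.assert_allclose(res["t"], ref.statistic, atol=1e-12)
        np.testing.assert_allclose(res["p_value"], ref.pvalue, atol=1e-12)

    def test_zero_variance_is_degenerate_with_p_one(self):
        res = paired_t(values_from_diffs(np.array([[1.0, 1.0, 1.0, 1.0]])), PAIRS4)
        assert res["degenerate"].iloc[0]
        assert res["p_value"].iloc[0] == 1.0

    def test_two_pairs_gives_df_one(self):
        res = paired_t(values_from_diffs(np.array([[0.5, -0.1]])), PAIRS4[:2])
        assert res["df"].iloc[0] == 1

    def test_sign_symmetry(self):
        rng = np.random.default_rng(6)
        d = rng.normal(size=(50, 4))
        res = paired_t(values_from_diffs(d), PAIRS4)
        neg = paired_t(values_from_diffs(-d), PAIRS4)
        np.testing.assert_allclose(neg["t"], -res["t"], atol=1e-12)
        np.testing.assert_allclose(neg["p_value"], res["p_value"], atol=1e-12)

    def test_input_validation(self):
        vals = values_from_diffs(np.zeros((2, 4)))
        with pytest.raises(ValueError, match="two pairs"):
            paired_t(vals, PAIRS4[:1])
        with pytest.raises(ValueError, match="exactly one pair"):
            paired_t(vals, [("a1", "b1"), ("a1", "b2")])

    def test_type_one_error_calibrated_under_null(self):
        rng = np.random.default_rng(2024)
        d = rng.normal(size=(10_000, 4))
        res = paired_t(values_from_diffs(d), PAIRS4)
        rate = (res["p_value"] < 0.05).mean()
        assert 0.043 <= rate <= 0.057


class TestFoldChange:
    def test_planted_mean_difference(self):
        vals = pd.DataFrame({"a1": [0.0], "a2": [0.0], "b1": [-1.89], "b2": [-1.89]})
        fc = log2_fold_change(vals, ["b1", "b2"], ["a1", "a2"])
        assert fc.iloc[0] == pytest.approx(-1.89)

    def test_equal_means_zero_and_antisymmetry(self):
        rng = np.random.default_rng(7)
        vals = pd.DataFrame(rng.normal(size=(30, 4)), columns=["a1", "a2", "b1", "b2"])
        fc = log2_fold_change(vals, ["b1", "b2"], ["a1", "a2"])
        rev = log2_fold_change(vals, ["a1", "a2"], ["b1", "b2"])
        np.testing.assert_allclose(fc, -rev, atol=1e-12)
        same = log2_fold_change(vals, ["a1", "a2"], ["a1", "a2"])
        np.testing.assert_allclose(same, 0, atol=1e-12)

    def test_empty_group_rejected(self):
        vals = pd.DataFrame({"a1": [0.0]})
        with pytest.raises(ValueError):
            log2_fold_change(vals, [], ["a1"])


class TestModeratedT:
    def test_identical_variances_shrink_to_fixed_point(self):
        s_sq = np.full(50, 0.04)
        eff = np.linspace(-1, 1, 50)
        res, prior = moderated_t(s_sq, 3.0, eff, 0.5)
        np.testing.assert_allclose(
            res["t_mod"], eff / (0.2 * 0.5), rtol=1e-6
        )

    def test_forced_infinite_prior_uses_s0_exactly(self):
        s_sq = np.array([0.01, 0.05, 0.2])
        res, _ = moderated_t(
            s_sq, 3.0, np.ones(3), 1.0, prior=EBPrior(d0=math.inf, s0_sq=0.04)
        )
        np.testing.assert_allclose(res["t_mod"], 1.0 / 0.2, rtol=1e-12)
        assert math.isinf(res["df_total"].iloc[0])

    def test_parameter_recovery_scaled_inverse_chi_square(self):
        rng = np.random.default_rng(8)
        d0_true, s0_true, d = 4.0, 0.04, 3.0
        n = 5000
        sigma2 = d0_true * s0_true / rng.chisquare(d0_true, size=n)
        s_sq = sigma2 * rng.chisquare(d, size=n) / d
        prior = fit_eb_prior(s_sq, d)
        assert abs(prior.d0 - d0_true) / d0_true < 0.30
        assert abs(prior.s0_sq - s0_true) / s0_true < 0.10

    def test_homogeneous_variance_ranking_matches_classical(self):
        rng = np.random.default_rng(9)
        n_pairs = 40  # enough replication for variance estimates to stabilize
        d = rng.normal(0, 0.3, size=(2000, n_pairs)) + rng.normal(0, 0.2, size=(2000, 1))
        pairs = [(f"a{j + 1}", f"b{j + 1}") for j in range(n_pairs)]
        vals = values_from_diffs(d)
        classical = paired_t(vals, pairs)
        moderated, prior = moderated_paired_t(vals, pairs)
        rho = stats.spearmanr(
            np.abs(classical["t"]), np.abs(moderated["t_mod"])
        ).statistic
        assert rho > 0.99
        assert prior.d0 > n_pairs  # strong shrinkage when variances are homogeneous

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_eb_prior(np.zeros(10), 3.0)
        with pytest.raises(ValueError):
            fit_eb_prior(np.array([0.1]), 3.0)

    def test_trigamma_inverse_roundtrip(self):
        from scipy.special import polygamma

        for y in (0.01, 0.5, 2.0, 50.0):
            x = trigamma_inverse(y)
            assert abs(float(polygamma(1, x)) - y) < 1e-8 * max(1, y)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.04])[0] == pytest.approx(0.04)

    def test_hand_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_matches_hand_oracle_on_random_vectors(self):
        def oracle(p):
            p = np.asarray(p, dtype=float)
            n = len(p)
            order = np.argsort(p)
            adj = p[order] * n / np.arange(1, n + 1)
            adj = np.minimum.accumulate(adj[::-1])[::-1]
            out = np.empty(n)
            out[order] = np.minimum(adj, 1.0)
            return out

        rng = np.random.default_rng(10)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_fdr(p), oracle(p), atol=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.2])


class TestVolcano:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (-1.89, 8.8e-6, "down"),
            (1.5, 0.001, "up"),
            (0.5, 0.001, "ns"),
            (-1.0, 0.01, "ns"),    # strict inequality at the FC boundary
            (-1.5, 0.05, "ns"),    # strict inequality at the p boundary
            (2.0, 0.2, "ns"),
        ],
    )
    def test_rule(self, fc, p, expected):
        assert classify_volcano(np.array([fc]), np.array([p]))[0] == expected


class TestSummarizeDirection:
    def test_all_negative(self):
        res = pd.DataFrame({"log2_fc": [-1.0, -0.5], "p_value": [0.01, 0.2]})
        s = summarize_direction(res)
        assert s["frac_negative"] == 1.0 and s["frac_negative_significant"] == 1.0

    def test_null_simulation_balanced(self):
        rng = np.random.default_rng(12)
        d = rng.normal(size=(10_000, 4))
        res = paired_t(values_from_diffs(d), PAIRS4)
        s = summarize_direction(res)
        assert abs(s["frac_negative"] - 0.5) < 0.02

    def test_global_hypo_shift_enriches_negative_fraction_among_hits(self):
        rng = np.random.default_rng(13)
        d = rng.normal(-0.15, 0.5, size=(5000, 4))
        res = paired_t(values_from_diffs(d), PAIRS4)
        s = summarize_direction(res)
        assert s["frac_negative_significant"] > s["frac_negative"] > 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_direction(pd.DataFrame({"log2_fc": [], "p_value": []}))


def test_unpaired_welch_available_for_unknown_designs():
    rng = np.random.default_rng(14)
    vals = pd.DataFrame(rng.normal(size=(100, 4)), columns=["a1", "a2", "b1", "b2"])
    res = unpaired_t(vals, ["b1", "b2"], ["a1", "a2"])
    ref = stats.ttest_ind(
        vals[["b1", "b2"]].to_numpy(), vals[["a1", "a2"]].to_numpy(), axis=1, equal_var=False
    )
    np.testing.assert_allclose(res["t"], ref.statistic, atol=1e-12)
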