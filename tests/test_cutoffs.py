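"""Mixture cutoff EM, equal-posterior root, Youden and dual thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from npqflow import (
    DualCutoffs,
    GaussianMixtureCutoff,
    YoudenCutoff,
    dual_cutoffs,
    equal_posterior_cutoff,
    fit_two_component_gmm,
    pet_reference,
    youden_cutoff,
)
from npqflow.cutoffs import _em_once


def draw_mixture(rng, n, w1, mu1, s1, mu2, s2):
    lab = rng.random(n) < (1 - w1)
    return np.where(lab, rng.normal(mu2, s2, n), rng.normal(mu1, s1, n)), lab


class TestGMM:
    def test_parameter_recovery_large_n(self):
        """EM recovers (w, mu, sigma) of a well-separated mixture within 0.05."""
        rng = np.random.default_rng(100)
        x, _ = draw_mixture(rng, 10_000, 0.5, -1.0, 0.5, 1.0, 0.5)
        model = fit_two_component_gmm(x, seed=0)
        mean, sd = model.standardization_  # undo the internal z-scoring
        mu = mean + sd * model.means_
        sg = sd * model.sigmas_
        assert model.weights_[0] == pytest.approx(0.5, abs=0.05)
        assert mu[0] == pytest.approx(-1.0, abs=0.05)
        assert mu[1] == pytest.approx(1.0, abs=0.05)
        assert sg[0] == pytest.approx(0.5, abs=0.05)
        assert sg[1] == pytest.approx(0.5, abs=0.05)
        assert model.converged_

    def test_em_loglik_monotone(self):
        """The EM objective never decreases across iterations."""
        rng = np.random.default_rng(7)
        x, _ = draw_mixture(rng, 2000, 0.4, -1.2, 0.6, 0.9, 0.4)
        x = (x - x.mean()) / x.std()
        w = np.array([0.5, 0.5])
        mu = np.array([-0.5, 0.5])
        var = np.array([1.0, 1.0])
        trace = []
        params = (w, mu, var)
        for _ in range(50):
            params, ll, _, _ = _em_once(x, *params, tol=0.0, max_iter=1)
            trace.append(ll)
        diffs = np.diff(trace)
        assert (diffs >= -1e-9).all()

    def test_agrees_with_sklearn_mixture(self):
        """Independent EM implementation (sklearn) lands on the same optimum."""
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(21)
        x, _ = draw_mixture(rng, 5000, 0.45, -1.0, 0.45, 1.1, 0.55)
        model = fit_two_component_gmm(x, seed=0)
        z = model.zscore(x)
        gm = GaussianMixture(2, n_init=5, random_state=0, tol=1e-8).fit(z[:, None])
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(model.means_, gm.means_.ravel()[order], atol=0.02)
        np.testing.assert_allclose(model.weights_, gm.weights_[order], atol=0.02)
        np.testing.assert_allclose(
            model.sigmas_, np.sqrt(gm.covariances_.ravel()[order]), atol=0.02
        )

    def test_unimodal_input_flagged_low_confidence(self):
        rng = np.random.default_rng(5)
        model = fit_two_component_gmm(rng.normal(0, 1, 3000), seed=0)
        assert model.low_confidence_

    def test_cutoff_scales_consistent(self):
        rng = np.random.default_rng(6)
        x, _ = draw_mixture(rng, 4000, 0.5, -1.0, 0.4, 1.0, 0.4)
        log10_vals = 3.67 + 0.2 * x
        model = fit_two_component_gmm(log10_vals, seed=0)
        assert model.cutoff_linear_ == pytest.approx(10 ** model.cutoff_log10_)
        mean, sd = model.standardization_
        assert model.cutoff_log10_ == pytest.approx(mean + sd * model.z_cutoff_)

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError, match="20"):
            fit_two_component_gmm(np.arange(10.0))


class TestEqualPosterior:
    def test_symmetric_case_is_zero(self):
        assert equal_posterior_cutoff([0.5, 0.5], [-1, 1], [1, 1]) == pytest.approx(0.0)

    def test_equal_variance_closed_form(self):
        """Higher weight on the upper component pulls the boundary down."""
        z = equal_posterior_cutoff([0.3, 0.7], [-1, 1], [0.8, 0.8])
        expect = 0.0 + 0.8**2 * np.log(0.3 / 0.7) / 2
        assert z == pytest.approx(expect, abs=1e-12)
        assert z < 0
        # and it satisfies the density balance it claims to solve
        assert 0.3 * norm.pdf(z, -1, 0.8) == pytest.approx(
            0.7 * norm.pdf(z, 1, 0.8), rel=1e-10
        )

    def test_unequal_variance_matches_bisection_oracle(self):
        """Quadratic root equals a brentq solve of the posterior balance."""
        cases = [
            (0.3, -1.0, 0.5, 1.0, 0.8),
            (0.6, -0.8, 0.55, 0.9, 0.55),
            (0.52, -0.80, 0.55, 0.867, 0.548),
            (0.45, -2.0, 1.0, 1.5, 0.3),
        ]
        for w1, m1, s1, m2, s2 in cases:
            got = equal_posterior_cutoff([w1, 1 - w1], [m1, m2], [s1, s2])

            def balance(z):
                return w1 * norm.pdf(z, m1, s1) - (1 - w1) * norm.pdf(z, m2, s2)

            oracle = brentq(balance, m1, m2, xtol=1e-12)
            assert got == pytest.approx(oracle, abs=1e-6)

    def test_posteriors_equal_at_cutoff(self):
        w, mu, sg = [0.4, 0.6], [-1.1, 0.9], [0.6, 0.5]
        z = equal_posterior_cutoff(w, mu, sg)
        p1 = w[0] * norm.pdf(z, mu[0], sg[0])
        p2 = w[1] * norm.pdf(z, mu[1], sg[1])
        assert abs(p1 - p2) / (p1 + p2) < 1e-6

    def test_overlapping_components_error(self):
        with pytest.raises(ValueError, match="overlap"):
            equal_posterior_cutoff([0.999, 0.001], [-0.05, 0.05], [1.0, 1.0])


class TestYouden:
    def test_separable_case(self):
        res = youden_cutoff([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.threshold == 0.8
        assert res.youden_j == pytest.approx(1.0)

    def test_matches_brute_force(self):
        """Vectorized scan equals exhaustive candidate evaluation, 200 instances."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(10, 60))
            s = rng.normal(0, 1, n).round(2)  # ties on purpose
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            res = youden_cutoff(s, y)
            best_j, best_t = -np.inf, None
            for t in np.unique(s):
                pred = s >= t
                sens = (pred & (y == 1)).sum() / (y == 1).sum()
                spec = (~pred & (y == 0)).sum() / (y == 0).sum()
                j = sens + spec - 1
                if j > best_j:  # first (smallest) threshold wins ties
                    best_j, best_t = j, t
            assert res.threshold == best_t
            assert res.youden_j == pytest.approx(best_j)

    def test_degenerate_equal_scores(self):
        res = youden_cutoff([1.0, 1.0, 1.0, 1.0], [0, 1, 0, 1])
        assert res.degenerate
        assert res.youden_j == pytest.approx(0.0)

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            youden_cutoff([1, 2, 3], [1, 1, 1])


class TestDualCutoffs:
    def test_perfect_separation_empty_intermediate(self):
        s = np.r_[np.zeros(30), np.ones(30)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        res = dual_cutoffs(s, y)
        assert res.n_intermediate == 0

    def test_training_sample_targets_met(self):
        """Sensitivity at lower and specificity at upper hit 95% by construction."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s0 = rng.normal(0, 1, 1000)
            s1 = rng.normal(2, 1, 1000)
            s = np.r_[s0, s1]
            y = np.r_[np.zeros(1000, int), np.ones(1000, int)]
            res = dual_cutoffs(s, y)
            sens_at_lower = (s1 >= res.lower).mean()
            spec_at_upper = (s0 < res.upper).mean()
            assert sens_at_lower >= 0.95
            assert spec_at_upper >= 0.95
            assert res.lower <= res.upper

    def test_trichotomy_counts_sum_and_monotone(self):
        rng = np.random.default_rng(2)
        s = np.r_[rng.normal(0, 1, 200), rng.normal(2, 1, 200)]
        y = np.r_[np.zeros(200, int), np.ones(200, int)]
        model = DualCutoffs().fit(s, y)
        classes = model.predict(s)
        res = model.result_
        assert res.n_low + res.n_intermediate + res.n_high == len(s)
        order = {"low": 0, "intermediate": 1, "high": 2}
        ranks = np.array([order[c] for c in classes])
        srt = np.argsort(s)
        assert (np.diff(ranks[srt]) >= 0).all()  # monotone in score


class TestPetReference:
    @pytest.fixture()
    def meta(self):
        return pd.DataFrame(
            {
                "sample_id": ["a", "b", "c", "d", "e"],
                "amyloid_pet": [21.0, 19.0, 20.0, np.nan, 75.0],
                "tau_pet": [1.6, 1.5, 1.2, 2.0, np.nan],
                "csf_ab_ratio": [0.05, 0.0673, 0.09, np.nan, 0.03],
            }
        )

    def test_amyloid_rule_and_boundary(self, meta):
        lab = pet_reference(meta, "amyloid")
        assert lab["a"] == 1 and lab["b"] == 0 and lab["e"] == 1
        assert lab["c"] == 0  # exactly 20 CL is negative
        assert "d" not in lab.index

    def test_tau_rule(self, meta):
        lab = pet_reference(meta, "tau")
        assert lab["a"] == 1  # SUVR 1.6 positive
        assert lab["b"] == 0 and lab["c"] == 0 and lab["d"] == 1

    def test_csf_rule(self, meta):
        lab = pet_reference(meta, "csf")
        assert lab["a"] == 1 and lab["b"] == 0 and lab["c"] == 0 and lab["e"] == 1


def test_gmm_and_youden_cutoffs_agree_when_separated():
    """On a well-separated mixture the two cutoff schemes nearly coincide."""
    rng = np.random.default_rng(31)
    x, lab = draw_mixture(rng, 10_000, 0.5, -1.0, 0.5, 1.0, 0.5)
    gmm = fit_two_component_gmm(x, seed=0)
    you = youden_cutoff(gmm.zscore(x), lab.astype(int))
    assert abs(gmm.z_cutoff_ - you.threshold) < 0.1
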