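"""Second-level hierarchy: design, Bayesian model reduction, PEB, search."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from gripdcm.inversion import GaussianBelief
from gripdcm.peb import (GAMMA_PRIOR_MEAN, GAMMA_PRIOR_VAR, DesignMatrix,
                         ImproperReductionError, bmr, build_design_matrix,
                         extract_subject_estimates, fit_peb, greedy_search_bma)


from tests_helpers_peb import make_fake_fits  # noqa: E402


class TestDesignMatrix:
    def test_hand_computed_two_subject_design(self):
        dm = build_design_matrix([0.0, 1.0], [1, 2])
        expect = np.array([[1.0, -0.5, -0.5, 0.0], [1.0, 0.5, 0.5, 0.0]])
        assert np.allclose(dm.X, expect)

    def test_columns_mean_centred(self):
        rng = np.random.default_rng(0)
        dm = build_design_matrix(rng.normal(0, 1, 20), np.repeat([1, 2, 3, 4], 5))
        assert np.all(np.abs(dm.X[:, 1:].mean(axis=0)) < 1e-10)
        assert np.all(dm.X[:, 0] == 1.0)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        perf = rng.normal(0, 1, 12)
        groups = np.repeat([1, 2, 3], 4)
        perm = rng.permutation(12)
        a = build_design_matrix(perf, groups).X
        b = build_design_matrix(perf[perm], groups[perm]).X
        assert np.allclose(a[perm], b)

    def test_dummy_coding_expands_group_columns(self):
        rng = np.random.default_rng(2)
        perf = rng.normal(0, 1, 12)
        groups = np.repeat(["g1", "g2", "g3"], 4)
        dm = build_design_matrix(perf, groups, age_coding="dummy")
        assert dm.X.shape == (12, 6)
        assert dm.names[:2] == ("commonalities", "performance")
        assert np.all(np.abs(dm.X[:, 1:].mean(axis=0)) < 1e-10)
        with pytest.raises(ValueError, match="age_coding"):
            build_design_matrix(perf, groups, age_coding="helmert")

    def test_constant_performance_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            build_design_matrix(np.ones(6), [1, 1, 1, 2, 2, 2])

    def test_uncentred_regressor_rejected(self):
        with pytest.raises(ValueError, match="centred"):
            DesignMatrix(np.array([[1.0, 2.0], [1.0, 3.0]]), names=("c", "x"))


def linear_gaussian_log_evidence(y, X, prior, noise_prec):
    C = X @ prior.cov @ X.T + np.eye(y.size) / noise_prec
    d = y - X @ prior.mean
    _, ld = np.linalg.slogdet(2 * np.pi * C)
    return float(-0.5 * (ld + d @ np.linalg.solve(C, d)))


class TestBMR:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.X = rng.normal(0, 1, (10, 3))
        self.noise_prec = 25.0
        self.prior = GaussianBelief(np.zeros(3), np.diag([0.5, 0.4, 0.3]))
        self.y = self.X @ np.array([0.5, -0.3, 0.0]) + rng.normal(0, 0.2, 10)
        P = self.noise_prec * self.X.T @ self.X + np.linalg.inv(self.prior.cov)
        S = np.linalg.inv(P)
        self.post = GaussianBelief(S @ (self.noise_prec * self.X.T @ self.y), S)

    def test_identity_reduction_is_neutral(self):
        dF, red = bmr(self.prior, self.post, self.prior)
        assert dF == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(red.mean, self.post.mean)
        assert np.allclose(red.cov, self.post.cov)

    def test_matches_conjugate_evidence_difference(self):
        # brute-force marginal likelihoods under full and pinned priors
        reduced = GaussianBelief(np.zeros(3), np.diag([0.5, 0.4, 1e-8]))
        dF, red = bmr(self.prior, self.post, reduced)
        oracle = (linear_gaussian_log_evidence(self.y, self.X, reduced, self.noise_prec)
                  - linear_gaussian_log_evidence(self.y, self.X, self.prior, self.noise_prec))
        assert dF == pytest.approx(oracle, abs=1e-3)
        # reduced posterior matches the direct conjugate computation
        P_r = self.noise_prec * self.X.T @ self.X + np.linalg.inv(reduced.cov)
        mu_r = np.linalg.solve(P_r, self.noise_prec * self.X.T @ self.y)
        assert np.allclose(red.mean, mu_r, atol=1e-6)

    def test_pinning_a_supported_parameter_costs_evidence(self):
        reduced = GaussianBelief(np.zeros(3), np.diag([1e-8, 0.4, 0.3]))
        dF, _ = bmr(self.prior, self.post, reduced)
        assert dF < 0

    def test_improper_reduction_raises(self):
        wide = GaussianBelief(np.zeros(3), 100.0 * np.eye(3))
        loose_post = GaussianBelief(np.zeros(3), 5.0 * np.eye(3))
        prior = GaussianBelief(np.zeros(3), np.eye(3))
        with pytest.raises(ImproperReductionError):
            bmr(prior, loose_post, wide)


class TestFitPEB:
    def test_intercept_only_recovers_group_mean(self):
        rng = np.random.default_rng(3)
        theta = 0.3 + rng.normal(0, 0.05, (12, 2))
        fits, _ = make_fake_fits(theta, rng=rng)
        X = DesignMatrix(np.ones((12, 1)), names=("commonalities",))
        peb = fit_peb(fits, X)
        mean_post = np.mean([f.posterior.mean for f in fits], axis=0)
        assert np.allclose(peb.beta.mean, mean_post, atol=2 * peb.beta.sd().max())

    def test_matches_brute_force_hierarchical_oracle(self):
        # tiny problem: exact marginal likelihood over a fine gamma grid,
        # beta by direct GLS on the joint Gaussian
        rng = np.random.default_rng(4)
        n, p = 6, 2
        theta = rng.normal(0, 0.2, (n, p))
        fits, t_obs = make_fake_fits(theta, like_prec=200.0, rng=rng)
        X = DesignMatrix(np.ones((n, 1)), names=("commonalities",))
        peb = fit_peb(fits, X)

        B = (1.0 / 8.0) * np.eye(p)
        A = np.vstack([np.kron(X.X[i], np.eye(p)) for i in range(n)])
        tvec = t_obs.ravel()
        best = (-np.inf, None)
        for g in np.arange(0.0, 12.0, 0.005):
            S = np.kron(np.eye(n), np.eye(p) / 200.0 + np.exp(-g) * np.eye(p))
            C = A @ B @ A.T + S
            ll = multivariate_normal.logpdf(tvec, mean=np.zeros(n * p), cov=C)
            ll += -0.5 * ((g - GAMMA_PRIOR_MEAN) ** 2 / GAMMA_PRIOR_VAR
                          + np.log(2 * np.pi * GAMMA_PRIOR_VAR))
            if ll > best[0]:
                Sb = np.linalg.inv(A.T @ np.linalg.solve(S, A) + np.linalg.inv(B))
                mb = Sb @ A.T @ np.linalg.solve(S, tvec)
                best = (ll, (g, mb))
        g_star, beta_star = best[1]
        assert peb.rfx_precision == pytest.approx(g_star, abs=0.05)
        assert np.allclose(peb.beta.mean, beta_star, atol=1e-3)
        assert peb.F == pytest.approx(best[0], abs=0.05)

    def test_planted_performance_effect_recovered_with_small_bias(self):
        biases = []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n, p = 40, 4
            perf = rng.normal(0, 0.3, n)
            groups = np.repeat([1, 2, 3, 4], 10)
            X = build_design_matrix(perf, groups)
            beta = np.zeros((4, p))
            beta[1, 2] = 0.3                       # performance -> edge 3
            theta = X.X @ beta + rng.normal(0, 0.05, (n, p))
            fits, _ = make_fake_fits(theta, rng=rng)
            peb = fit_peb(fits, X)
            est = peb.beta_matrix()[1, 2]
            assert np.sign(est) == 1.0
            biases.append(est - 0.3)
        assert np.max(np.abs(biases)) < 0.1

    def test_misaligned_design_rejected(self):
        rng = np.random.default_rng(5)
        fits, _ = make_fake_fits(rng.normal(0, 0.1, (4, 2)), rng=rng)
        with pytest.raises(ValueError):
            fit_peb(fits, DesignMatrix(np.ones((5, 1)), names=("c",)))


class TestGreedySearchBMA:
    def _small_peb(self, seed=6, n=20, p=3, beta_row=(0.4, 0.0, 0.0)):
        rng = np.random.default_rng(seed)
        theta = np.array(beta_row) + rng.normal(0, 0.05, (n, p))
        fits, _ = make_fake_fits(theta, rng=rng)
        X = DesignMatrix(np.ones((n, 1)), names=("commonalities",))
        return fit_peb(fits, X)

    def test_matches_exhaustive_enumeration_exactly(self):
        # independent exhaustive BMA over all 2^3 reduced models
        import itertools
        from gripdcm.peb import _reduced_prior
        from scipy.special import logsumexp

        peb = self._small_peb()
        res = greedy_search_bma(peb)

        dFs, masks, means, variances = [], [], [], []
        for comb in itertools.product([False, True], repeat=3):
            off = [i for i, o in enumerate(comb) if o]
            if off:
                dF, post = bmr(peb.beta_prior, peb.beta,
                               _reduced_prior(peb.beta_prior, off))
            else:
                dF, post = 0.0, peb.beta
            dFs.append(dF)
            masks.append([i not in off for i in range(3)])
            means.append(post.mean)
            variances.append(np.diag(post.cov))
        dFs = np.array(dFs)
        w = np.exp(dFs - logsumexp(dFs))
        masks = np.array(masks)
        mean = w @ np.array(means)
        pp = w @ masks
        assert np.allclose(res.mean, mean, atol=1e-10)
        assert np.allclose(res.pp, pp, atol=1e-10)
        # models more than 20 nats below the best carry ~e-20 weight and are
        # dropped from the average without affecting it
        assert res.model_masks.shape[0] <= 8
        assert res.model_weights.sum() == pytest.approx(1.0)

    def test_supported_effect_retained_null_pruned(self):
        peb = self._small_peb()
        res = greedy_search_bma(peb, threshold=0.95)
        assert res.pp[0] > 0.95 and res.retained[0]
        assert res.pp[1] <= 0.95 and res.pp[2] <= 0.95

    def test_sensitivity_and_specificity_across_seeds(self):
        hits, false_pos = 0, []
        for seed in range(10):
            peb = self._small_peb(seed=200 + seed, n=40, p=4,
                                  beta_row=(0.4, 0.0, 0.0, 0.0))
            res = greedy_search_bma(peb)
            hits += res.pp[0] > 0.95 and res.mean[0] > 0
            false_pos.append(np.mean(res.pp[1:] > 0.95))
        assert hits >= 9
        assert np.mean(false_pos) <= 0.1

    def test_greedy_blocks_handle_more_than_eight_effects(self):
        rng = np.random.default_rng(7)
        n, p = 30, 10
        theta = np.r_[0.4, np.zeros(9)] + rng.normal(0, 0.05, (n, p))
        fits, _ = make_fake_fits(theta, rng=rng)
        peb = fit_peb(fits, DesignMatrix(np.ones((n, 1)), names=("c",)))
        res = greedy_search_bma(peb)
        assert res.pp[0] > 0.95
        assert np.all(res.pp[1:] < 0.95)
        assert len(res.search_trace) >= 1

    def test_pp_equivariant_under_effect_relabelling(self):
        peb = self._small_peb(seed=8, beta_row=(0.0, 0.4, 0.0))
        res = greedy_search_bma(peb)
        peb2 = self._small_peb(seed=8, beta_row=(0.0, 0.4, 0.0))
        assert np.allclose(greedy_search_bma(peb2).pp, res.pp)
        assert res.pp[1] > 0.95


class TestExtractSubjectEstimates:
    def test_scalar_precision_weighting(self):
        # one coupling, weak first-level prior: the empirical-prior update is
        # the hand-derived convex combination of data and group prediction
        rng = np.random.default_rng(9)
        like_prec = 50.0
        theta = np.array([[0.6], [0.2], [0.4], [0.4]])
        fits, t_obs = make_fake_fits(theta, like_prec=like_prec,
                                     prior_var=1e6, rng=rng)
        X = DesignMatrix(np.ones((4, 1)), names=("c",))
        peb = fit_peb(fits, X)
        est = extract_subject_estimates(peb, fits)
        m = peb.beta.mean[0]
        emp_var = np.exp(-peb.rfx_precision) + peb.beta.cov[0, 0]
        expect = (like_prec * t_obs[:, 0] + m / emp_var) / (like_prec + 1 / emp_var)
        assert np.allclose(est[:, 0], expect, atol=1e-3)

    def test_shrinkage_limits(self):
        rng = np.random.default_rng(10)
        theta = rng.normal(0.3, 0.1, (6, 2))
        fits, t_obs = make_fake_fits(theta, prior_var=1e6, rng=rng)
        X = DesignMatrix(np.ones((6, 1)), names=("c",))
        peb = fit_peb(fits, X)
        # between-subject variance -> infinity: no shrinkage
        peb.rfx_precision = -30.0
        est = extract_subject_estimates(peb, fits)
        assert np.allclose(est, t_obs, atol=1e-3)
        # between-subject variance -> 0: full shrinkage to the group prediction
        peb.rfx_precision = 30.0
        peb.beta.cov = 1e-12 * np.eye(2)
        est = extract_subject_estimates(peb, fits)
        pred = peb.X @ peb.beta.mean.reshape(1, 2)
        assert np.allclose(est, pred, atol=1e-3)
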