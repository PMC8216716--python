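"""Variational Laplace: free energy, evidence identities, model fitting."""

import numpy as np
import pytest

from gripdcm.inversion import (FitOptions, GaussianBelief, Hyperprior, csd_vector,
                               _unvectorize, fit_dcm, free_energy,
                               variance_explained)
from gripdcm.neuralmass import predict_csd
from gripdcm.spectral import CrossSpectra, hermitize


class LinearForward:
    """Toy linear-Gaussian forward map with an exact evidence."""

    def __init__(self, X, prior):
        self.X = np.asarray(X, float)
        self.prior = prior

    def predict(self, theta):
        return self.X @ theta

    def posterior(self, y, lam):
        prec = np.exp(lam)
        P = prec * self.X.T @ self.X + np.linalg.inv(self.prior.cov)
        S = np.linalg.inv(P)
        mu = S @ (prec * self.X.T @ y
                  + np.linalg.inv(self.prior.cov) @ self.prior.mean)
        return GaussianBelief(mu, S)

    def log_evidence(self, y, lam):
        C = self.X @ self.prior.cov @ self.X.T + np.exp(-lam) * np.eye(y.size)
        d = y - self.X @ self.prior.mean
        _, ld = np.linalg.slogdet(2 * np.pi * C)
        return float(-0.5 * (ld + d @ np.linalg.solve(C, d)))


def hermitian_noise(rng, shape, scale):
    E = scale * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape)) / np.sqrt(2)
    return hermitize(E)


class TestVectorization:
    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        G = hermitize(rng.normal(0, 1, (7, 4, 4)) + 1j * rng.normal(0, 1, (7, 4, 4)))
        vec = csd_vector(G)
        assert vec.size == 7 * 16
        assert np.allclose(_unvectorize(vec, 7, 4), G)


class TestVarianceExplained:
    def test_perfect_prediction_is_100(self, model, freqs):
        cs = predict_csd(model, freqs)
        assert variance_explained(cs, cs) == pytest.approx(100.0)

    def test_zero_prediction_is_0(self, model, freqs):
        cs = predict_csd(model, freqs)
        zero = CrossSpectra(freqs, np.zeros_like(cs.G))
        assert variance_explained(zero, cs) == pytest.approx(0.0)

    def test_two_bin_hand_computation(self):
        y = CrossSpectra([1.0, 2.0], np.array([[[4.0]], [[2.0]]], dtype=complex))
        p = CrossSpectra([1.0, 2.0], np.array([[[3.0]], [[2.0]]], dtype=complex))
        # SS_res = 1, SS_tot = 16 + 4 = 20
        assert variance_explained(p, y) == pytest.approx(100 * (1 - 1 / 20))

    def test_zero_data_rejected(self):
        z = CrossSpectra([1.0], np.zeros((1, 2, 2), dtype=complex))
        with pytest.raises(ValueError):
            variance_explained(z, z)


class TestFreeEnergy:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.X = rng.normal(0, 1, (12, 3))
        self.prior = GaussianBelief(np.zeros(3), 0.5 * np.eye(3))
        self.fwd = LinearForward(self.X, self.prior)
        self.y = self.X @ np.array([0.3, -0.2, 0.1]) + rng.normal(0, 0.1, 12)

    def test_kl_terms_vanish_at_prior_and_hE(self):
        hyper = Hyperprior(hE=4.0, hC=0.1)
        F = free_energy(self.fwd, self.prior, 4.0, self.y, hyper=hyper)
        # accuracy-only reference: expected log-likelihood at the prior
        r = self.y - self.X @ self.prior.mean
        tr = np.einsum("ij,jk,ik->", self.X, self.prior.cov, self.X)
        acc = (-0.5 * np.exp(4.0) * (r @ r + tr)
               + 0.5 * self.y.size * (4.0 - np.log(2 * np.pi)))
        assert F == pytest.approx(acc, abs=1e-9)

    def test_equals_exact_log_evidence_at_exact_posterior(self):
        lam = np.log(1 / 0.1**2)
        q = self.fwd.posterior(self.y, lam)
        F = free_energy(self.fwd, q, lam, self.y, hyper=Hyperprior(hE=lam, hC=0.05))
        assert F == pytest.approx(self.fwd.log_evidence(self.y, lam), abs=1e-6)

    def test_irrelevant_parameter_never_increases_evidence(self):
        # orthogonal extra regressor; data generated by the smaller model
        rng = np.random.default_rng(2)
        x1 = rng.normal(0, 1, 16)
        x2 = rng.normal(0, 1, 16)
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)
        y = 0.3 * x1
        lam = np.log(1 / 0.2**2)
        hyper = Hyperprior(hE=lam, hC=0.05)
        f1 = LinearForward(x1[:, None], GaussianBelief([0.0], [[0.5]]))
        f2 = LinearForward(np.column_stack([x1, x2]),
                           GaussianBelief(np.zeros(2), 0.5 * np.eye(2)))
        F1 = free_energy(f1, f1.posterior(y, lam), lam, y, hyper=hyper)
        F2 = free_energy(f2, f2.posterior(y, lam), lam, y, hyper=hyper)
        assert F2 <= F1 + 1e-6


class TestFitDCM:
    def test_self_consistency_from_truth(self, model, freqs):
        th = np.zeros(14)
        th[[1, 8]] = [0.3, -0.3]
        data = predict_csd(model.with_couplings(th), freqs)
        full = np.zeros(14)
        fit = fit_dcm(data, model,
                      opts=FitOptions(free="couplings", init=th, max_iter=6))
        assert fit.r2 >= 99.0
        assert np.allclose(fit.posterior.mean, th, atol=0.05)

    def test_free_energy_monotone_and_posterior_psd(self, model, freqs):
        rng = np.random.default_rng(3)
        th = rng.normal(0, 0.2, 14)
        cs = predict_csd(model.with_couplings(th), freqs)
        scale = 0.01 * np.sqrt(np.mean(np.abs(cs.G) ** 2))
        data = CrossSpectra(freqs, cs.G + hermitian_noise(rng, cs.G.shape, scale))
        fit = fit_dcm(data, model, opts=FitOptions(free="couplings", max_iter=16))
        assert np.all(np.diff(fit.F_trace) >= -1e-6)
        assert np.linalg.eigvalsh(fit.posterior.cov).min() > 0

    def test_credible_interval_coverage_on_replicates(self, model, freqs):
        # 90 % marginal CI should cover each planted coupling in >= 8/10
        # noise replicates when the noise hyperprior can adapt
        edges = [2, 7, 12]
        th = np.zeros(14)
        th[edges] = [0.4, -0.4, 0.4]
        truth = predict_csd(model.with_couplings(th), freqs)
        scale = 0.005 * np.sqrt(np.mean(np.abs(truth.G) ** 2))
        rng = np.random.default_rng(42)
        hits = np.zeros(len(edges))
        n_rep = 10
        for _ in range(n_rep):
            data = CrossSpectra(freqs, truth.G + hermitian_noise(rng, truth.G.shape, scale))
            fit = fit_dcm(data, model, hyper=Hyperprior(hE=18.0, hC=1.0),
                          opts=FitOptions(free="couplings", max_iter=16))
            sd = fit.posterior.sd()
            lo = fit.posterior.mean - 1.645 * sd
            hi = fit.posterior.mean + 1.645 * sd
            hits += (lo[edges] <= th[edges]) & (th[edges] <= hi[edges])
        assert np.all(hits >= 0.8 * n_rep)

    def test_tight_prior_clamps_posterior_to_prior_mean(self, model, freqs):
        th = np.zeros(14)
        th[0] = 0.4
        data = predict_csd(model.with_couplings(th), freqs)
        clamped = model.with_couplings(np.zeros(14))
        clamped.prior_cov = model.prior_cov.copy()
        clamped.prior_cov[0, 0] = 1e-10
        fit = fit_dcm(data, clamped, opts=FitOptions(free="couplings", max_iter=12))
        assert abs(fit.posterior.mean[0]) < 1e-3

    def test_free_parameter_subset_by_name(self, model, freqs):
        from gripdcm.inversion import DCMForward
        fwd = DCMForward(model, freqs, free=["A:lateral:PMv->SMA", "b:amp"])
        assert fwd.n_free == 2
        assert set(fwd.prior.names) == {"A:lateral:PMv->SMA", "b:amp"}
        with pytest.raises(ValueError, match="unknown"):
            DCMForward(model, freqs, free=["A:nope"])
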