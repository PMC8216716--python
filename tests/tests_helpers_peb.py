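"""Shared builders for second-level tests: fabricated subject fits."""

import numpy as np

from gripdcm.inversion import FitResult, GaussianBelief
from gripdcm.peb import DesignMatrix, fit_peb


def make_fake_fits(theta_true, like_prec=400.0, prior_var=1.0 / 8.0, rng=None,
                   obs=None):
    """Subject fits with known likelihood precision around true couplings."""
    n, p = theta_true.shape
    names = tuple(f"A:forward:n{i}->m{i}" for i in range(p))
    P0 = np.eye(p) / prior_var
    fits, t_obs = [], []
    for i in range(n):
        t = theta_true[i] + rng.normal(0, 1 / np.sqrt(like_prec), p) \
            if obs is None else obs[i]
        P = like_prec * np.eye(p) + P0
        S = np.linalg.inv(P)
        mu = S @ (like_prec * t)
        fits.append(FitResult(
            posterior=GaussianBelief(mu, S, names=names), F=0.0, r2=100.0,
            predicted=None, n_iter=1, converged=True,
            prior=GaussianBelief(np.zeros(p), prior_var * np.eye(p), names=names),
            lam=GaussianBelief([18.0], [[1.0]])))
        t_obs.append(t)
    return fits, np.array(t_obs)


def make_fake_peb(seed=0, n=20, p=3, beta_row=(0.4, 0.0, 0.0)):
    rng = np.random.default_rng(seed)
    theta = np.array(beta_row) + rng.normal(0, 0.05, (n, p))
    fits, _ = make_fake_fits(theta, rng=rng)
    X = DesignMatrix(np.ones((n, 1)), names=("commonalities",))
    return fit_peb(fits, X)
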