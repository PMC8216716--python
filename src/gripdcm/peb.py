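"""Parametric empirical Bayes over subject-level coupling posteriors.

The hierarchical model places a Gaussian general linear model over the 14
extrinsic log-couplings θ_i of each subject:

    θ_i = X_i β + ε_i,     ε_i ~ N(0, exp(−γ)·I),     β ~ N(0, B),

where X collects mean-centred between-subject regressors (intercept /
commonalities, precision-grip performance, ordinal age-group code, and
their interaction). Because first-level posteriors are Gaussian, each
subject's evidence as a function of its coupling prior is available in
closed form (Bayesian model reduction), so the second level never
revisits spectra: subject fits are summarised by the data precision
Λ_i = Σ_i⁻¹ − C0⁻¹ implied by their posterior (Σ_i) and prior (C0), and
the GLM is estimated by maximizing the second-level free energy over the
between-subject log precision γ with the β posterior in closed form.

Bayesian model reduction (:func:`bmr`) scores any reduced prior against
the full model's fit; a greedy search over all combinations of
second-level effects switched off (prior variance → 0) followed by
Bayesian model averaging yields per-effect posterior probabilities, which
are thresholded at > 0.95 by convention.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.special import logsumexp

from .inversion import FitResult, GaussianBelief

LN2PI = np.log(2.0 * np.pi)

REGRESSOR_NAMES = ("commonalities", "performance", "age_group", "interaction")

#: default second-level settings
BETA_PRIOR_VAR = 1.0 / 8.0        # matches first-level coupling prior variance
GAMMA_PRIOR_MEAN = 4.0            # between-subject log precision
GAMMA_PRIOR_VAR = 1.0 / 64.0
PIN_VARIANCE = 1e-8               # "switched off" prior variance
BMA_NAT_WINDOW = 20.0             # models this far below the best are dropped


class ImproperReductionError(ValueError):
    """Reduced-prior precision update left a non-positive-definite matrix."""


@dataclass
class DesignMatrix:
    """Between-subject design: intercept plus mean-centred regressors."""

    X: np.ndarray
    names: tuple[str, ...] = REGRESSOR_NAMES

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if len(self.names) != self.X.shape[1]:
            raise ValueError("one name per design column required")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the intercept")
        if self.X.shape[1] > 1:
            means = np.abs(self.X[:, 1:].mean(axis=0))
            if np.any(means > 1e-10):
                raise ValueError("regressors 2..k must be mean-centred")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]


def build_design_matrix(performance, age_group, age_coding: str = "ordinal") -> DesignMatrix:
    """[1, centred performance, centred age code(s), centred interaction(s)].

    With ``age_coding="ordinal"`` (default) groups are coded 1..K in sorted
    label order as a single mean-centred column and the interaction is the
    re-centred product of the two centred columns. With
    ``age_coding="dummy"`` each non-reference group contributes a centred
    indicator column plus a matching performance interaction.
    """
    perf = np.asarray(performance, dtype=float)
    groups = np.asarray(age_group)
    if perf.size != groups.size:
        raise ValueError("performance and age_group must align")
    labels = sorted(set(groups.tolist()))
    if len(labels) < 2:
        raise ValueError("need at least two distinct groups")
    if np.ptp(perf) == 0:
        warnings.warn("constant performance regressor is degenerate", stacklevel=2)
    pc = perf - perf.mean()
    if age_coding == "ordinal":
        code = np.array([labels.index(g) + 1 for g in groups], dtype=float)
        ac = code - code.mean()
        inter = pc * ac
        inter = inter - inter.mean()
        X = np.column_stack([np.ones(perf.size), pc, ac, inter])
        return DesignMatrix(X=X)
    if age_coding == "dummy":
        cols, names = [np.ones(perf.size), pc], ["commonalities", "performance"]
        dummies = []
        for g in labels[1:]:
            d = (groups == g).astype(float)
            dummies.append(d - d.mean())
            names.append(f"age_{g}")
        inters = []
        for g, d in zip(labels[1:], dummies):
            i = pc * d
            inters.append(i - i.mean())
            names.append(f"interaction_{g}")
        X = np.column_stack(cols + dummies + inters)
        return DesignMatrix(X=X, names=tuple(names))
    raise ValueError(f"unknown age_coding {age_coding!r}")


# ---------------------------------------------------------------------------
# Bayesian model reduction

def bmr(full_prior: GaussianBelief, full_post: GaussianBelief,
        reduced_prior: GaussianBelief) -> tuple[float, GaussianBelief]:
    """Evidence change and posterior under a reduced prior, in closed form.

    With posterior precision P, prior precision P0 and reduced-prior
    precision R0, the reduced posterior has precision P_r = P + R0 − P0 and
    the log-evidence change is

        dF = ½[ln|R0| − ln|P0| + ln|P| − ln|P_r|]
           + ½[μ0ᵀP0μ0 − ν0ᵀR0ν0 + μ_rᵀP_rμ_r − μᵀPμ].
    """
    P = np.linalg.inv(full_post.cov)
    P0 = np.linalg.inv(full_prior.cov)
    R0 = np.linalg.inv(reduced_prior.cov)
    mu, mu0, nu0 = full_post.mean, full_prior.mean, reduced_prior.mean

    Pr = P + R0 - P0
    Pr = 0.5 * (Pr + Pr.T)
    eig = np.linalg.eigvalsh(Pr)
    if eig.min() <= 0:
        raise ImproperReductionError("reduced posterior precision not positive definite")
    mu_r = np.linalg.solve(Pr, P @ mu + R0 @ nu0 - P0 @ mu0)

    def _ld(A):
        sign, ld = np.linalg.slogdet(A)
        return ld

    dF = 0.5 * (_ld(R0) - _ld(P0) + _ld(P) - _ld(Pr)) \
        + 0.5 * (mu0 @ P0 @ mu0 - nu0 @ R0 @ nu0 + mu_r @ Pr @ mu_r - mu @ P @ mu)
    reduced_post = GaussianBelief(mu_r, np.linalg.inv(Pr), names=full_post.names)
    return float(dF), reduced_post


# ---------------------------------------------------------------------------
# second-level fit

@dataclass
class PEBResult:
    """Second-level effect posterior and the summaries it was built from."""

    beta: GaussianBelief              # vec over (regressor, edge), regressor-major
    F: float
    rfx_precision: float              # γ̂: between-subject log precision
    X: np.ndarray
    edge_names: tuple[str, ...]
    regressor_names: tuple[str, ...]
    beta_prior: GaussianBelief
    t: np.ndarray                     # de-shrunk subject estimates (n × p)
    Lambda: np.ndarray                # per-subject data precisions (n × p × p)
    F_trace: list

    @property
    def n_effects(self) -> int:
        return self.beta.dim

    def beta_matrix(self) -> np.ndarray:
        """β as (regressors × edges)."""
        return self.beta.mean.reshape(len(self.regressor_names), len(self.edge_names))


def _coupling_summaries(fits: list[FitResult]) -> tuple[np.ndarray, np.ndarray, tuple[str, ...], np.ndarray]:
    """Per-subject de-shrunk estimates t_i and data precisions Λ_i.

    Λ_i = Σ_i⁻¹ − C0⁻¹ on the coupling sub-block (eigenvalue-floored so the
    pseudo-data t_i = Λ_i⁻¹ Σ_i⁻¹ (μ_i − shrinkage) are defined even for
    directions the data left uninformed).
    """
    names0 = [n for n in fits[0].posterior.names if n.startswith("A:")]
    if not names0:
        raise ValueError("fits carry no extrinsic coupling parameters")
    for f in fits:
        if [n for n in f.posterior.names if n.startswith("A:")] != names0:
            raise ValueError("subjects do not share the coupling parameterization")
    p = len(names0)
    n = len(fits)
    t = np.empty((n, p))
    Lam = np.empty((n, p, p))
    C0_sub = None
    for i, f in enumerate(fits):
        idx = [list(f.posterior.names).index(nm) for nm in names0]
        Si = f.posterior.cov[np.ix_(idx, idx)]
        mi = f.posterior.mean[idx]
        C0 = f.prior.cov[np.ix_(idx, idx)]
        m0 = f.prior.mean[idx]
        C0_sub = C0
        Pi = np.linalg.inv(Si)
        P0 = np.linalg.inv(C0)
        L = Pi - P0
        L = 0.5 * (L + L.T)
        w, V = np.linalg.eigh(L)
        floor = max(1e-6, 1e-10 * max(w.max(), 1.0))
        L = (V * np.maximum(w, floor)) @ V.T
        t[i] = np.linalg.solve(L, Pi @ mi - P0 @ m0)
        Lam[i] = L
    return t, Lam, tuple(names0), C0_sub


def _peb_free_energy(gamma: float, t: np.ndarray, Lam: np.ndarray, X: np.ndarray,
                     B0: np.ndarray) -> tuple[float, GaussianBelief]:
    """Marginal free energy of the second-level GLM at log precision γ.

    Exact for the linear-Gaussian hierarchy: the β posterior is conjugate
    given γ, and the γ prior enters as a density term (γ treated as a
    point estimate).
    """
    n, p = t.shape
    q = X.shape[1]
    d = q * p
    Q = np.exp(-gamma) * np.eye(p)
    B0inv = np.linalg.inv(B0)

    P_beta = B0inv.copy()
    h = np.zeros(d)
    Sinvs = []
    lds = 0.0
    for i in range(n):
        S = np.linalg.inv(Lam[i]) + Q
        Sinv = np.linalg.inv(S)
        Sinvs.append(Sinv)
        _, ld = np.linalg.slogdet(S)
        lds += ld
        A = np.kron(X[i], np.eye(p))          # p × d
        P_beta += A.T @ Sinv @ A
        h += A.T @ Sinv @ t[i]
    Sigma_beta = np.linalg.inv(P_beta)
    mu_beta = Sigma_beta @ h

    F = 0.0
    for i in range(n):
        A = np.kron(X[i], np.eye(p))
        r = t[i] - A @ mu_beta
        F += -0.5 * (r @ Sinvs[i] @ r) - 0.5 * np.trace(Sinvs[i] @ A @ Sigma_beta @ A.T)
    F += -0.5 * lds - 0.5 * n * p * LN2PI

    # KL(q(β) ‖ p(β))
    _, ld_B0 = np.linalg.slogdet(B0)
    _, ld_Sb = np.linalg.slogdet(Sigma_beta)
    kl = 0.5 * (np.trace(B0inv @ Sigma_beta) + mu_beta @ B0inv @ mu_beta
                - d + ld_B0 - ld_Sb)
    F -= kl
    # γ prior (point estimate)
    F += -0.5 * ((gamma - GAMMA_PRIOR_MEAN) ** 2 / GAMMA_PRIOR_VAR
                 + np.log(2 * np.pi * GAMMA_PRIOR_VAR))
    return float(F), GaussianBelief(mu_beta, 0.5 * (Sigma_beta + Sigma_beta.T))


def fit_peb(fits: list[FitResult], X: DesignMatrix,
            beta_prior_var: float = BETA_PRIOR_VAR,
            gamma_bounds: tuple[float, float] = (-2.0, 12.0)) -> PEBResult:
    """Empirical-Bayes estimation of second-level effects β and RE precision.

    The β posterior is conjugate given γ; γ is optimized by golden-section
    over ``gamma_bounds`` after a coarse grid pass, recording a monotone
    trace of accepted free energies.
    """
    if X.n_subjects != len(fits):
        raise ValueError("design rows must align with subject fits")
    t, Lam, edge_names, _ = _coupling_summaries(fits)
    p, q = t.shape[1], X.n_regressors
    B0 = beta_prior_var * np.eye(q * p)
    prior_names = tuple(f"{r}:{e}" for r in X.names for e in edge_names)

    trace = []
    grid = np.linspace(gamma_bounds[0], gamma_bounds[1], 15)
    best_g, best_F, best_q = None, -np.inf, None
    for g in grid:
        F, qb = _peb_free_energy(g, t, Lam, X.X, B0)
        if F > best_F:
            best_g, best_F, best_q = g, F, qb
            trace.append(F)

    def neg(g):
        return -_peb_free_energy(float(g), t, Lam, X.X, B0)[0]

    lo = max(gamma_bounds[0], best_g - 1.5)
    hi = min(gamma_bounds[1], best_g + 1.5)
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-4})
    if -res.fun > best_F:
        best_g, best_F = float(res.x), float(-res.fun)
        best_F, best_q = _peb_free_energy(best_g, t, Lam, X.X, B0)
        trace.append(best_F)

    beta = GaussianBelief(best_q.mean, best_q.cov, names=prior_names)
    return PEBResult(beta=beta, F=best_F, rfx_precision=best_g, X=X.X,
                     edge_names=edge_names, regressor_names=tuple(X.names),
                     beta_prior=GaussianBelief(np.zeros(q * p), B0, names=prior_names),
                     t=t, Lambda=Lam, F_trace=trace)


# ---------------------------------------------------------------------------
# greedy search and Bayesian model averaging

@dataclass
class BMAResult:
    mean: np.ndarray
    sd: np.ndarray
    pp: np.ndarray
    retained: np.ndarray
    names: tuple[str, ...]
    threshold: float
    model_masks: np.ndarray          # final model set, models × effects (True = on)
    model_weights: np.ndarray
    search_trace: list

    def table(self):
        import pandas as pd
        reg, edge = zip(*(n.split(":", 1) for n in self.names))
        return pd.DataFrame({"regressor": reg, "edge": edge, "mean": self.mean,
                             "sd": self.sd, "pp": self.pp, "retained": self.retained})


def _reduced_prior(base: GaussianBelief, off: np.ndarray) -> GaussianBelief:
    cov = base.cov.copy()
    mean = base.mean.copy()
    off = np.asarray(off)
    cov[off, :] = 0.0
    cov[:, off] = 0.0
    cov[off, off] = PIN_VARIANCE
    mean[off] = 0.0
    return GaussianBelief(mean, cov, names=base.names)


def _search_models(peb: PEBResult, candidates: list[int], fixed_off: set[int]):
    """Score all 2^|candidates| on/off combinations of candidate effects."""
    d = peb.n_effects
    masks, dFs, posts = [], [], []
    for comb in itertools.product([False, True], repeat=len(candidates)):
        off = set(fixed_off)
        off.update(c for c, is_off in zip(candidates, comb) if is_off)
        mask = np.ones(d, dtype=bool)
        mask[list(off)] = False
        if off:
            dF, post = bmr(peb.beta_prior, peb.beta,
                           _reduced_prior(peb.beta_prior, sorted(off)))
        else:
            dF, post = 0.0, peb.beta
        masks.append(mask)
        dFs.append(dF)
        posts.append(post)
    return np.array(masks), np.array(dFs), posts


def _bma(masks, dFs, posts, names, threshold):
    keep = dFs >= dFs.max() - BMA_NAT_WINDOW
    masks, dFs = masks[keep], dFs[keep]
    posts = [p for p, k in zip(posts, keep) if k]
    logw = dFs - logsumexp(dFs)
    w = np.exp(logw)
    means = np.stack([p.mean for p in posts])
    variances = np.stack([np.diag(p.cov) for p in posts])
    mean = w @ means
    second = w @ (variances + means**2)
    sd = np.sqrt(np.clip(second - mean**2, 0.0, None))
    pp = w @ masks
    return BMAResult(mean=mean, sd=sd, pp=pp, retained=pp > threshold,
                     names=names, threshold=threshold, model_masks=masks,
                     model_weights=w, search_trace=[])


def greedy_search_bma(peb: PEBResult, threshold: float = 0.95,
                      block: int = 8) -> BMAResult:
    """Prune second-level effects by iterated exhaustive reduction, then BMA.

    With ≤ ``block`` free effects the 2^k model space is searched
    exhaustively. Otherwise effects are ranked by the evidence change of
    removing each alone; the ``block`` least-contributing are searched
    exhaustively, effects switched off in the winning model are pruned,
    and the process repeats until nothing more is pruned. The final model
    set is averaged with softmax evidence weights; pp(effect) is the
    summed weight of models containing it.
    """
    d = peb.n_effects
    trace = []
    pruned: set[int] = set()
    while True:
        active = [i for i in range(d) if i not in pruned]
        if len(active) <= block:
            candidates = active
        else:
            single = {}
            for e in active:
                try:
                    single[e], _ = bmr(peb.beta_prior, peb.beta,
                                       _reduced_prior(peb.beta_prior,
                                                      sorted(pruned | {e})))
                except ImproperReductionError:
                    single[e] = -np.inf
            # largest dF = least contribution when removed; ties broken by index
            candidates = sorted(active, key=lambda e: (-single[e], e))[:block]
            candidates = sorted(candidates)
        masks, dFs, posts = _search_models(peb, candidates, pruned)
        best = int(np.argmax(dFs))
        newly_off = [c for c in candidates if not masks[best][c]]
        trace.append({"candidates": candidates, "pruned": sorted(pruned),
                      "best_dF": float(dFs[best]), "newly_off": newly_off})
        if len(active) <= block or not newly_off:
            result = _bma(masks, dFs, posts, peb.beta.names, threshold)
            result.search_trace.extend(trace)
            return result
        pruned.update(newly_off)


def extract_subject_estimates(peb: PEBResult, fits: list[FitResult],
                              bma: BMAResult | None = None) -> np.ndarray:
    """Re-evaluate subject couplings under empirical (group-level) priors.

    Each subject's first-level coupling posterior is re-referenced by
    Bayesian model reduction to a prior centred on the group prediction
    X_i β with covariance exp(−γ̂)·I + A_i Σ_β A_iᵀ. Returns the updated
    posterior means, subjects × couplings.
    """
    beta = bma.mean if bma is not None else peb.beta.mean
    Sigma_b = peb.beta.cov
    p = len(peb.edge_names)
    n = peb.X.shape[0]
    Q = np.exp(-peb.rfx_precision) * np.eye(p)
    out = np.empty((n, p))
    for i, f in enumerate(fits):
        idx = [list(f.posterior.names).index(nm) for nm in peb.edge_names]
        post = GaussianBelief(f.posterior.mean[idx], f.posterior.cov[np.ix_(idx, idx)])
        prior = GaussianBelief(f.prior.mean[idx], f.prior.cov[np.ix_(idx, idx)])
        A = np.kron(peb.X[i], np.eye(p))
        emp_mean = A @ beta
        emp_cov = Q + A @ Sigma_b @ A.T
        _, red = bmr(prior, post, GaussianBelief(emp_mean, emp_cov))
        out[i] = red.mean
    return out
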