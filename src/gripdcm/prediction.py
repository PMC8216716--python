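"""Out-of-sample prediction of performance and age from coupling estimates.

Leave-one-out cross-validation (LOOCV): per fold, an ordinary
least-squares multiple regression of the target on the 14 coupling
estimates is fitted to the remaining subjects and applied to the held-out
one. Classification of age group uses quadratic discriminant analysis
(class-conditional Gaussians with class-specific shrinkage-regularized
covariances, priors = training class frequencies), also leave-one-out,
with an exact binomial accuracy CI and a one-sided exact binomial test
against the no-information rate (largest class share).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

QDA_SHRINKAGE = 1e-6   # Σ_k + shrinkage·tr(Σ_k)/p·I


@dataclass
class FeatureTable:
    """Subjects × couplings with the targets the study predicts."""

    features: np.ndarray
    performance: np.ndarray
    age_months: np.ndarray
    age_group: np.ndarray
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.performance = np.asarray(self.performance, dtype=float)
        self.age_months = np.asarray(self.age_months, dtype=float)
        self.age_group = np.asarray(self.age_group)
        n = self.features.shape[0]
        if not (self.performance.size == self.age_months.size == self.age_group.size == n):
            raise ValueError("targets must align with feature rows")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("missing or non-finite feature cells")
        if not self.feature_names:
            self.feature_names = tuple(f"edge{i+1}" for i in range(self.features.shape[1]))

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame, feature_cols=None) -> "FeatureTable":
        """Build from the (subject, group, performance, age_months, edges…) layout."""
        if feature_cols is None:
            reserved = {"subject", "subject_id", "group", "age_group",
                        "performance", "age_months"}
            feature_cols = [c for c in df.columns if c not in reserved]
        return cls(features=df[feature_cols].to_numpy(),
                   performance=df["performance"].to_numpy(),
                   age_months=df["age_months"].to_numpy(),
                   age_group=df["group" if "group" in df else "age_group"].to_numpy(),
                   feature_names=tuple(feature_cols))

    def target(self, name: str) -> np.ndarray:
        if name == "performance":
            return self.performance
        if name == "age_months":
            return self.age_months
        raise ValueError(f"unknown numeric target {name!r}")


@dataclass
class CVResult:
    rmse: float
    r2: float                 # squared Pearson correlation, predicted vs observed
    r2_ss: float              # 1 − SSE/SST alternative, also reported
    predictions: np.ndarray
    observed: np.ndarray


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    labels: tuple
    accuracy: float
    ci95: tuple[float, float]
    p_vs_nir: float
    nir: float
    predictions: np.ndarray = field(default=None)

    def normalized(self) -> np.ndarray:
        """Rows normalized to the true-class sizes (rows sum to 1)."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)


def loocv_regression(t: FeatureTable, target: str) -> CVResult:
    """Leave-one-out OLS prediction of a numeric target from the couplings."""
    y = t.target(target)
    n, p = t.features.shape
    if n < p + 2:
        raise ValueError("need at least p + 2 subjects for LOOCV regression")
    X = np.column_stack([np.ones(n), t.features])
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xt, yt = X[mask], y[mask]
        if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
            warnings.warn(f"rank-deficient fold {i}; ridge fallback", stacklevel=2)
            lam = 1e-8 * np.trace(Xt.T @ Xt) / Xt.shape[1]
            coef = np.linalg.solve(Xt.T @ Xt + lam * np.eye(Xt.shape[1]), Xt.T @ yt)
        else:
            coef, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        preds[i] = X[i] @ coef
    rmse = float(np.sqrt(np.mean((preds - y) ** 2)))
    r = float(np.corrcoef(preds, y)[0, 1])
    sst = float(np.sum((y - y.mean()) ** 2))
    r2_ss = float(1.0 - np.sum((y - preds) ** 2) / sst)
    return CVResult(rmse=rmse, r2=r**2, r2_ss=r2_ss, predictions=preds, observed=y)


def _qda_fit(X: np.ndarray, y: np.ndarray, labels):
    params = {}
    n = X.shape[0]
    p = X.shape[1]
    for lab in labels:
        sel = X[y == lab]
        if sel.shape[0] < 2:
            raise ValueError(f"class {lab!r} has fewer than two training members")
        mu = sel.mean(axis=0)
        S = np.cov(sel, rowvar=False)
        S = S + QDA_SHRINKAGE * (np.trace(S) / p) * np.eye(p)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError(f"singular covariance for class {lab!r} after shrinkage")
        params[lab] = (mu, np.linalg.inv(S), logdet, np.log(sel.shape[0] / n))
    return params


def qda_predict(params, x: np.ndarray):
    best, best_d = None, -np.inf
    for lab, (mu, Sinv, logdet, logpi) in params.items():
        d = -0.5 * logdet - 0.5 * (x - mu) @ Sinv @ (x - mu) + logpi
        if d > best_d:
            best, best_d = lab, d
    return best


def qda_loocv(t: FeatureTable) -> ConfusionMatrix:
    """Leave-one-out QDA classification of age group from the couplings."""
    labels = tuple(sorted(set(t.age_group.tolist())))
    counts_by = {lab: int(np.sum(t.age_group == lab)) for lab in labels}
    if min(counts_by.values()) < 2:
        raise ValueError("every class needs at least two members")
    preds = np.empty(t.n, dtype=object)
    for i in range(t.n):
        mask = np.ones(t.n, dtype=bool)
        mask[i] = False
        params = _qda_fit(t.features[mask], t.age_group[mask], labels)
        preds[i] = qda_predict(params, t.features[i])
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for true, pred in zip(t.age_group, preds):
        counts[labels.index(true), labels.index(pred)] += 1
    correct = int(np.trace(counts))
    nir = max(counts_by.values()) / t.n
    test = stats.binomtest(correct, t.n)
    ci = test.proportion_ci(confidence_level=0.95, method="exact")
    return ConfusionMatrix(counts=counts, labels=labels,
                           accuracy=correct / t.n,
                           ci95=(float(ci.low), float(ci.high)),
                           p_vs_nir=nir_test(correct, t.n, nir),
                           nir=nir, predictions=preds)


def nir_test(correct: int, n: int, nir: float) -> float:
    """One-sided exact binomial tail P(X ≥ correct | n, nir)."""
    if not 0 <= correct <= n:
        raise ValueError("correct must be within 0..n")
    if not 0.0 < nir < 1.0:
        raise ValueError("nir must be in (0, 1)")
    return float(stats.binomtest(correct, n, nir, alternative="greater").pvalue)
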