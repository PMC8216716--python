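"""Spatial-mode projection and cross-spectral density estimation.

Multichannel recordings are reduced to a few variance-ordered orthonormal
spatial modes (the data features the generative model is fitted to), and
auto-/cross-spectra of those modes are estimated on a 1-Hz grid over the
analysis band, either from a least-squares multivariate autoregression
(analysis-grade) or by Welch's averaged periodogram (display-grade).

Spectral densities follow the one-sided convention of
:func:`scipy.signal.welch` (units² / Hz), so the two estimators and the
analytic model spectra are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal


class SpectralError(ValueError):
    """Raised for empty bands, rank-deficient projections or unstable fits."""


@dataclass
class ChannelTimeSeries:
    """A multichannel recording: ``data`` is channels × samples (µV)."""

    data: np.ndarray
    rate: float
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite samples in recording")
        if not self.labels:
            self.labels = tuple(f"ch{i:02d}" for i in range(self.data.shape[0]))
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class SpectralModes:
    """Orthonormal spatial projection and the projected series.

    ``projection`` is modes × channels with orthonormal rows;
    ``series`` is modes × samples.
    """

    projection: np.ndarray
    series: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.projection = np.asarray(self.projection, dtype=float)
        self.series = np.asarray(self.series, dtype=float)
        if self.projection.shape[0] != self.series.shape[0]:
            raise ValueError("projection and series disagree on mode count")

    @property
    def n_modes(self) -> int:
        return self.projection.shape[0]


@dataclass
class CrossSpectra:
    """Hermitian cross-spectral matrices on an ascending frequency grid.

    ``G`` has shape (n_freqs, n_modes, n_modes); each slice is Hermitian
    with real nonnegative diagonal for proper spectra (observation noise
    added downstream may perturb positive semidefiniteness, not symmetry).
    """

    freqs: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.G = np.asarray(self.G, dtype=complex)
        if self.G.ndim != 3 or self.G.shape[0] != self.freqs.size:
            raise ValueError("G must be (n_freqs, m, m) matching freqs")
        if self.G.shape[1] != self.G.shape[2]:
            raise ValueError("cross-spectral matrices must be square")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequencies must be strictly ascending")

    @property
    def n_modes(self) -> int:
        return self.G.shape[1]

    def hermitian_error(self) -> float:
        return float(np.max(np.abs(self.G - self.G.conj().transpose(0, 2, 1))))

    def copy(self) -> "CrossSpectra":
        return CrossSpectra(self.freqs.copy(), self.G.copy())


def hermitize(G: np.ndarray) -> np.ndarray:
    """Project each frequency slice onto the Hermitian subspace."""
    G = np.asarray(G, dtype=complex)
    return 0.5 * (G + G.conj().transpose(0, 2, 1))


def project_to_modes(x: ChannelTimeSeries, n_modes: int) -> SpectralModes:
    """Project channels onto their leading principal spatial modes.

    The projection rows are the leading left singular vectors of the
    mean-removed channel data, so mode 1 carries the largest variance
    share and rows are orthonormal.
    """
    if n_modes < 1 or n_modes > x.n_channels:
        raise SpectralError(f"n_modes must be in 1..{x.n_channels}")
    if x.n_samples <= x.n_channels:
        raise SpectralError("need more samples than channels")
    centred = x.data - x.data.mean(axis=1, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    tol = s[0] * max(centred.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if n_modes > rank:
        raise SpectralError(f"requested {n_modes} modes but data rank is {rank}")
    projection = u[:, :n_modes].T
    return SpectralModes(projection=projection, series=projection @ centred, rate=x.rate)


def _band(fmin: float, fmax: float, rate: float) -> np.ndarray:
    if fmax >= rate / 2:
        raise SpectralError("fmax must be below the Nyquist frequency")
    freqs = np.arange(np.ceil(fmin), np.floor(fmax) + 1.0)
    if freqs.size == 0:
        raise SpectralError("empty frequency band")
    return freqs


def fit_mar(series: np.ndarray, order: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares multivariate autoregression.

    Returns (A, sigma): coefficient stack (order, m, m) and innovation
    covariance (m, m). Raises :class:`SpectralError` if the fitted model
    is unstable (companion eigenvalue on or outside the unit circle).
    """
    series = np.atleast_2d(series)
    m, n = series.shape
    if order < 1:
        raise SpectralError("AR order must be >= 1")
    if n <= order * m + 1:
        raise SpectralError("series too short for requested order")
    y = series[:, order:].T                          # (n-order, m)
    lags = np.concatenate([series[:, order - k: n - k].T for k in range(1, order + 1)], axis=1)
    coef, *_ = np.linalg.lstsq(lags, y, rcond=None)  # (order*m, m)
    resid = y - lags @ coef
    sigma = resid.T @ resid / (y.shape[0] - order * m)
    A = coef.T.reshape(m, order, m).transpose(1, 0, 2)
    # companion-form stability check
    comp = np.zeros((order * m, order * m))
    comp[:m, :] = np.concatenate(list(A), axis=1)
    if order > 1:
        comp[m:, :-m] = np.eye((order - 1) * m)
    if np.max(np.abs(np.linalg.eigvals(comp))) >= 1.0:
        raise SpectralError("fitted autoregression is unstable")
    return A, sigma


def mar_spectrum(A: np.ndarray, sigma: np.ndarray, freqs: np.ndarray, rate: float) -> np.ndarray:
    """One-sided analytic spectrum of a fitted autoregression."""
    order, m, _ = A.shape
    out = np.empty((freqs.size, m, m), dtype=complex)
    for i, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f / rate)
        Af = np.eye(m, dtype=complex)
        for k in range(order):
            Af -= A[k] * z ** (k + 1)
        H = np.linalg.inv(Af)
        out[i] = 2.0 * (H @ sigma @ H.conj().T) / rate
    return hermitize(out)


def estimate_csd(
    m: SpectralModes,
    fmin: float = 4.0,
    fmax: float = 48.0,
    method: str = "mar",
    order: int = 8,
) -> CrossSpectra:
    """Estimate Hermitian cross-spectra on a 1-Hz grid over [fmin, fmax].

    ``method="mar"`` fits a least-squares multivariate autoregression and
    evaluates its analytic spectrum; ``method="welch"`` averages windowed
    periodograms (Hann, 1-Hz resolution, 50 % overlap).
    """
    freqs = _band(fmin, fmax, m.rate)
    series = m.series
    if method == "mar":
        A, sigma = fit_mar(series, order)
        G = mar_spectrum(A, sigma, freqs, m.rate)
    elif method == "welch":
        nperseg = min(int(round(m.rate)), series.shape[1])
        f_all, _ = signal.welch(series[0], fs=m.rate, nperseg=nperseg)
        idx = np.array([int(np.argmin(np.abs(f_all - f))) for f in freqs])
        k = series.shape[0]
        G = np.empty((freqs.size, k, k), dtype=complex)
        # package convention: G[i, j] = E[X_i · conj(X_j)];
        # scipy's csd(x, y) returns conj(X)·Y, hence the conjugate
        for i in range(k):
            for j in range(i, k):
                _, gij = signal.csd(series[i], series[j], fs=m.rate, nperseg=nperseg)
                G[:, i, j] = np.conj(gij[idx])
                G[:, j, i] = gij[idx]
        G = hermitize(G)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CrossSpectra(freqs=freqs, G=G)
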