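"""Generative model of the cortical grasping network.

Five sources — IPL, M1, PMv, SMA, DLPFC — are each modelled as a
convolution-based neural mass with three populations (spiny stellate,
inhibitory interneuron, pyramidal). Population membrane potentials obey
second-order synaptic kernel dynamics

    v̈ = (H/τ)·m − (2/τ)·v̇ − v/τ²,

where ``m`` is presynaptic firing input, ``H`` the synaptic gain and τ the
time constant. Firing rates are a centred sigmoid of membrane potential
(slope ``s`` at the operating point); the model is linearized at the origin,
so predicted cross-spectra follow from the transfer function of the
linearized state space:

    G_y(f) = L·T(f)·G_u(f)·T(f)ᴴ·Lᴴ + G_n(f),   T(f) = C·(2πif·I − J)⁻¹·B,

with J the state Jacobian, B the innovations input map (innovations drive
the spiny-stellate populations), C the pyramidal depolarization read-out,
L the lead field, G_u the diagonal innovations spectrum
g_u(f) = exp(a1)·f^(−exp(a2)), and G_n power-law observation noise
(channel-specific plus common terms).

Extrinsic connections follow hierarchical targeting rules: forward
connections drive spiny-stellate populations, backward connections drive
pyramidal and inhibitory populations, lateral connections drive all three.
Each extrinsic connection is parameterized as a unit-less log-scaling of a
fixed baseline strength, so coupling priors are zero-mean in log space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .spectral import ChannelTimeSeries, CrossSpectra, hermitize

SOURCES: tuple[str, ...] = ("IPL", "M1", "PMv", "SMA", "DLPFC")

#: states per source: (v, v̇) for stellate, inhibitory, pyramidal-excitatory
#: and pyramidal-inhibitory compartments
N_STATES_PER_SOURCE = 8

#: baseline extrinsic strengths before exp(log-scaling)
BASELINE_STRENGTH = {"forward": 32.0, "backward": 16.0, "lateral": 4.0}


class UnstableModelError(RuntimeError):
    """The linearized network has a non-decaying eigenmode."""


@dataclass(frozen=True)
class NetworkGraph:
    """Directed extrinsic connectivity between named sources."""

    nodes: tuple[str, ...]
    forward: tuple[tuple[str, str], ...]
    backward: tuple[tuple[str, str], ...]
    lateral: tuple[tuple[str, str], ...]
    coordinates: dict | None = None

    def __post_init__(self) -> None:
        all_edges = list(self.forward) + list(self.backward) + list(self.lateral)
        for src, dst in all_edges:
            if src == dst:
                raise ValueError(f"self-edge {src}->{dst} not allowed")
            if src not in self.nodes or dst not in self.nodes:
                raise ValueError(f"edge endpoint outside node set: {src}->{dst}")
        if len({(k, e) for k, es in (("f", self.forward), ("b", self.backward),
                                     ("l", self.lateral)) for e in es}) != len(all_edges):
            raise ValueError("duplicate edge within a connection type")
        typed = [set(self.forward), set(self.backward), set(self.lateral)]
        if typed[0] & typed[1] or typed[0] & typed[2] or typed[1] & typed[2]:
            raise ValueError("forward/backward/lateral edge sets must be disjoint")

    def edges(self) -> list[tuple[str, str, str]]:
        """Canonical ordered edge list as (kind, src, dst)."""
        out = [("forward", s, d) for s, d in self.forward]
        out += [("backward", s, d) for s, d in self.backward]
        out += [("lateral", s, d) for s, d in self.lateral]
        return out

    @property
    def n_extrinsic(self) -> int:
        return len(self.forward) + len(self.backward) + len(self.lateral)


def build_grasping_network(coordinates: dict | None = None) -> NetworkGraph:
    """The a priori grasping network: 14 extrinsic connections.

    Backward (top-down) connections run DLPFC→PMv, DLPFC→SMA, PMv→M1,
    SMA→M1, PMv→IPL and SMA→IPL; forward connections are their reversals;
    PMv and SMA are reciprocally laterally connected.
    """
    backward = (("DLPFC", "PMv"), ("DLPFC", "SMA"), ("PMv", "M1"),
                ("SMA", "M1"), ("PMv", "IPL"), ("SMA", "IPL"))
    forward = tuple((d, s) for s, d in backward)
    lateral = (("PMv", "SMA"), ("SMA", "PMv"))
    return NetworkGraph(nodes=SOURCES, forward=forward, backward=backward,
                        lateral=lateral, coordinates=coordinates)


@dataclass(frozen=True)
class SourceParams:
    """Neural-mass constants shared by the three populations of a source.

    Defaults follow standard convolution-model conventions: excitatory and
    inhibitory kernels (τ_e = 4 ms, H_e = 8 mV; τ_i = 16 ms, H_i = 32 mV)
    and intrinsic coupling gains γ = 128·[1, 0.8, 0.25, 0.25] for the
    pyramidal→stellate, stellate→pyramidal, pyramidal→inhibitory and
    inhibitory→pyramidal projections. ``sigmoid_slope`` is the firing-rate
    gain at the operating point.
    """

    tau_e: float = 0.004
    tau_i: float = 0.016
    H_e: float = 8.0
    H_i: float = 32.0
    gamma: tuple[float, float, float, float] = (128.0, 102.4, 32.0, 32.0)
    sigmoid_slope: float = 0.175

    def __post_init__(self) -> None:
        if min(self.tau_e, self.tau_i, self.H_e, self.H_i) <= 0:
            raise ValueError("time constants and gains must be positive")
        if any(g <= 0 for g in self.gamma):
            raise ValueError("intrinsic gains must be positive")


@dataclass
class CouplingParams:
    """Log-scaling of extrinsic connection strengths, one per graph edge."""

    theta_A: np.ndarray
    theta_C: np.ndarray

    def __post_init__(self) -> None:
        self.theta_A = np.asarray(self.theta_A, dtype=float)
        self.theta_C = np.asarray(self.theta_C, dtype=float)

    @classmethod
    def zeros(cls, graph: NetworkGraph) -> "CouplingParams":
        return cls(np.zeros(graph.n_extrinsic), np.zeros(len(graph.nodes)))


@dataclass
class SpectralNuisance:
    """Innovations and observation-noise spectrum parameters.

    Innovations power is g_u(f) = exp(a1)·f^(−exp(a2)) per source; the
    default exponent parameter a2 = −32 makes exp(a2) ≈ 1e-14, i.e. a flat
    innovations spectrum. Observation noise has a channel-specific term
    (b) and a common term (c), each of the same power-law form.
    """

    a1: np.ndarray
    a2: np.ndarray
    b: tuple[float, float] = (-16.0, -32.0)
    c: tuple[float, float] = (-16.0, -32.0)

    def __post_init__(self) -> None:
        self.a1 = np.asarray(self.a1, dtype=float)
        self.a2 = np.asarray(self.a2, dtype=float)

    @classmethod
    def default(cls, n_sources: int) -> "SpectralNuisance":
        return cls(a1=np.zeros(n_sources), a2=np.full(n_sources, -32.0))

    def innovations_power(self, freqs: np.ndarray) -> np.ndarray:
        """(n_freqs, n_sources) innovations spectral density."""
        f = np.asarray(freqs, dtype=float)[:, None]
        return np.exp(self.a1)[None, :] * f ** (-np.exp(self.a2))[None, :]


# ---------------------------------------------------------------------------
# free-parameter bookkeeping

#: default prior variances per parameter class (log-scaling units)
PRIOR_VARIANCES = {"A": 1.0 / 8.0, "a1": 1.0 / 128.0, "a2": 1.0 / 128.0,
                   "b": 1.0 / 128.0, "c": 1.0 / 128.0}


def parameter_names(graph: NetworkGraph) -> list[str]:
    names = [f"A:{k}:{s}->{d}" for k, s, d in graph.edges()]
    names += [f"a1:{n}" for n in graph.nodes]
    names += [f"a2:{n}" for n in graph.nodes]
    names += ["b:amp", "b:exp", "c:amp", "c:exp"]
    return names


@dataclass
class DCMModel:
    """The full generative model: graph, masses, couplings, noise, lead field.

    ``priors`` holds the Gaussian prior over the free-parameter vector in
    the order given by :func:`parameter_names`; couplings and nuisance
    parameters are free by default, intrinsic mass constants are fixed.
    """

    graph: NetworkGraph
    sources: dict[str, SourceParams]
    coupling: CouplingParams
    nuisance: SpectralNuisance
    leadfield: np.ndarray
    prior_mean: np.ndarray = None
    prior_cov: np.ndarray = None

    def __post_init__(self) -> None:
        self.leadfield = np.atleast_2d(np.asarray(self.leadfield, dtype=float))
        n_nodes = len(self.graph.nodes)
        if self.leadfield.shape[1] != n_nodes:
            raise ValueError("lead field must have one column per source")
        if np.any(np.linalg.norm(self.leadfield, axis=0) == 0):
            raise ValueError("lead field columns must be nonzero")
        if self.coupling.theta_A.size != self.graph.n_extrinsic:
            raise ValueError("one coupling per extrinsic edge required")
        if self.prior_mean is None:
            self.prior_mean, self.prior_cov = default_priors(self.graph)
        if self.prior_mean.size != self.prior_cov.shape[0]:
            raise ValueError("prior mean and covariance dimensions differ")

    # -- parameter vector plumbing -----------------------------------------
    @property
    def names(self) -> list[str]:
        return parameter_names(self.graph)

    def free_vector(self) -> np.ndarray:
        return np.concatenate([
            self.coupling.theta_A,
            self.nuisance.a1,
            self.nuisance.a2,
            np.asarray(self.nuisance.b, dtype=float),
            np.asarray(self.nuisance.c, dtype=float),
        ])

    def with_free_vector(self, theta: np.ndarray) -> "DCMModel":
        theta = np.asarray(theta, dtype=float)
        n_e, n_s = self.graph.n_extrinsic, len(self.graph.nodes)
        if theta.size != n_e + 2 * n_s + 4:
            raise ValueError("free-parameter vector has wrong length")
        k = n_e
        coupling = CouplingParams(theta[:k], self.coupling.theta_C.copy())
        a1 = theta[k:k + n_s]
        a2 = theta[k + n_s:k + 2 * n_s]
        b = tuple(theta[k + 2 * n_s:k + 2 * n_s + 2])
        c = tuple(theta[k + 2 * n_s + 2:])
        nuis = SpectralNuisance(a1=a1, a2=a2, b=b, c=c)
        return replace(self, coupling=coupling, nuisance=nuis,
                       prior_mean=self.prior_mean, prior_cov=self.prior_cov)

    def with_couplings(self, theta_A: np.ndarray) -> "DCMModel":
        return replace(self, coupling=CouplingParams(np.asarray(theta_A, float),
                                                     self.coupling.theta_C.copy()))

    @property
    def n_modes(self) -> int:
        return self.leadfield.shape[0]

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        g = self.graph
        payload = {
            "nodes": list(g.nodes),
            "forward": [list(e) for e in g.forward],
            "backward": [list(e) for e in g.backward],
            "lateral": [list(e) for e in g.lateral],
            "coordinates": g.coordinates,
            "sources": {n: vars(self.sources[n]) | {"gamma": list(self.sources[n].gamma)}
                        for n in g.nodes},
            "theta_A": self.coupling.theta_A.tolist(),
            "theta_C": self.coupling.theta_C.tolist(),
            "a1": self.nuisance.a1.tolist(),
            "a2": self.nuisance.a2.tolist(),
            "b": list(self.nuisance.b),
            "c": list(self.nuisance.c),
            "leadfield": self.leadfield.tolist(),
            "prior_mean": self.prior_mean.tolist(),
            "prior_cov": self.prior_cov.tolist(),
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "DCMModel":
        d = json.loads(text)
        graph = NetworkGraph(nodes=tuple(d["nodes"]),
                             forward=tuple(tuple(e) for e in d["forward"]),
                             backward=tuple(tuple(e) for e in d["backward"]),
                             lateral=tuple(tuple(e) for e in d["lateral"]),
                             coordinates=d.get("coordinates"))
        sources = {n: SourceParams(tau_e=s["tau_e"], tau_i=s["tau_i"], H_e=s["H_e"],
                                   H_i=s["H_i"], gamma=tuple(s["gamma"]),
                                   sigmoid_slope=s["sigmoid_slope"])
                   for n, s in d["sources"].items()}
        return cls(graph=graph, sources=sources,
                   coupling=CouplingParams(np.array(d["theta_A"]), np.array(d["theta_C"])),
                   nuisance=SpectralNuisance(a1=np.array(d["a1"]), a2=np.array(d["a2"]),
                                             b=tuple(d["b"]), c=tuple(d["c"])),
                   leadfield=np.array(d["leadfield"]),
                   prior_mean=np.array(d["prior_mean"]),
                   prior_cov=np.array(d["prior_cov"]))


def default_priors(graph: NetworkGraph) -> tuple[np.ndarray, np.ndarray]:
    """Zero-centred log-scaling priors; innovations exponent centred at −32."""
    n_e, n_s = graph.n_extrinsic, len(graph.nodes)
    mean = np.concatenate([
        np.zeros(n_e),
        np.zeros(n_s),                 # a1
        np.full(n_s, -32.0),           # a2: flat innovations spectrum
        np.array([-16.0, -32.0]),      # b
        np.array([-16.0, -32.0]),      # c
    ])
    var = np.concatenate([
        np.full(n_e, PRIOR_VARIANCES["A"]),
        np.full(n_s, PRIOR_VARIANCES["a1"]),
        np.full(n_s, PRIOR_VARIANCES["a2"]),
        np.full(2, PRIOR_VARIANCES["b"]),
        np.full(2, PRIOR_VARIANCES["c"]),
    ])
    return mean, np.diag(var)


def default_leadfield(n_modes: int = 4, n_nodes: int = 5, seed: int = 2205) -> np.ndarray:
    """Synthetic fixed-gain lead field with unit-norm columns.

    A smooth random mixing matrix standing in for head-model gain; it is
    configuration, generated once from a fixed seed, and shared between
    data generation and model fitting.
    """
    rng = np.random.default_rng(seed)
    L = rng.standard_normal((n_modes, n_nodes))
    return L / np.linalg.norm(L, axis=0, keepdims=True)


def default_model(n_modes: int = 4, leadfield_seed: int = 2205,
                  sources: SourceParams | None = None) -> DCMModel:
    graph = build_grasping_network()
    src = sources or SourceParams()
    return DCMModel(graph=graph,
                    sources={n: src for n in graph.nodes},
                    coupling=CouplingParams.zeros(graph),
                    nuisance=SpectralNuisance.default(len(graph.nodes)),
                    leadfield=default_leadfield(n_modes, len(graph.nodes), leadfield_seed))


# ---------------------------------------------------------------------------
# dynamics

def _extrinsic_matrices(model: DCMModel) -> dict[str, np.ndarray]:
    """Dense (target, source) extrinsic strength matrices per edge kind."""
    idx = {n: i for i, n in enumerate(model.graph.nodes)}
    n = len(model.graph.nodes)
    mats = {k: np.zeros((n, n)) for k in ("forward", "backward", "lateral")}
    for e, (kind, s, d) in enumerate(model.graph.edges()):
        mats[kind][idx[d], idx[s]] = BASELINE_STRENGTH[kind] * np.exp(model.coupling.theta_A[e])
    return mats


def _population_input_weights(model: DCMModel) -> tuple[np.ndarray, ...]:
    """Presynaptic pyramidal-output weight matrices into each population.

    Returns (W1, W2, W3) mapping source pyramidal potentials to the firing
    input of stellate, inhibitory and pyramidal-excitatory compartments
    (intrinsic self terms included on the diagonal where applicable).
    """
    mats = _extrinsic_matrices(model)
    n = len(model.graph.nodes)
    g1 = np.array([model.sources[m].gamma[0] for m in model.graph.nodes])
    g3 = np.array([model.sources[m].gamma[2] for m in model.graph.nodes])
    W1 = np.diag(g1) + mats["forward"] + mats["lateral"]
    W2 = np.diag(g3) + mats["backward"] + mats["lateral"]
    W3 = mats["backward"] + mats["lateral"]
    return W1, W2, W3


def drift(model: DCMModel, x: np.ndarray, innovations: np.ndarray | None = None) -> np.ndarray:
    """Nonlinear state drift f(x) of the coupled neural masses.

    Used by tests to validate the analytic linearization by finite
    differences; the firing-rate nonlinearity is s·tanh(v) (centred, slope
    s at the origin).
    """
    nodes = model.graph.nodes
    n = len(nodes)
    x = np.asarray(x, dtype=float)
    u = np.zeros(n) if innovations is None else np.asarray(innovations, float)
    W1, W2, W3 = _population_input_weights(model)
    xr = x.reshape(n, N_STATES_PER_SOURCE)
    v1, d1, v2, d2, v3e, d3e, v3i, d3i = xr.T
    p = v3e - v3i

    slope = np.array([model.sources[m].sigmoid_slope for m in nodes])
    sig = lambda v: slope * np.tanh(v)      # noqa: E731 — centred sigmoid
    fp, f1, f2 = sig(p), sig(v1), sig(v2)

    te = np.array([model.sources[m].tau_e for m in nodes])
    ti = np.array([model.sources[m].tau_i for m in nodes])
    He = np.array([model.sources[m].H_e for m in nodes])
    Hi = np.array([model.sources[m].H_i for m in nodes])
    g2 = np.array([model.sources[m].gamma[1] for m in nodes])
    g4 = np.array([model.sources[m].gamma[3] for m in nodes])
    gain_u = np.exp(model.coupling.theta_C)

    out = np.empty_like(xr)
    out[:, 0] = d1
    out[:, 1] = (He / te) * (W1 @ fp + gain_u * u) - (2 / te) * d1 - v1 / te**2
    out[:, 2] = d2
    out[:, 3] = (He / te) * (W2 @ fp) - (2 / te) * d2 - v2 / te**2
    out[:, 4] = d3e
    out[:, 5] = (He / te) * (g2 * f1 + W3 @ fp) - (2 / te) * d3e - v3e / te**2
    out[:, 6] = d3i
    out[:, 7] = (Hi / ti) * (g4 * f2) - (2 / ti) * d3i - v3i / ti**2
    return out.ravel()


@dataclass
class Linearization:
    """State-space linearization at the operating point."""

    J: np.ndarray
    B: np.ndarray
    Cout: np.ndarray
    eigenvalues: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.eigenvalues is None:
            self.eigenvalues = np.linalg.eigvals(self.J)

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigenvalues.real < 0))


def linearize(model: DCMModel) -> Linearization:
    """Analytic Jacobian, innovations input map and pyramidal read-out.

    The sigmoid is replaced by its slope at the operating point (the
    origin), so the Jacobian is exact for the linearized dynamics.
    """
    nodes = model.graph.nodes
    n = len(nodes)
    ns = N_STATES_PER_SOURCE
    W1, W2, W3 = _population_input_weights(model)

    te = np.array([model.sources[m].tau_e for m in nodes])
    ti = np.array([model.sources[m].tau_i for m in nodes])
    He = np.array([model.sources[m].H_e for m in nodes])
    Hi = np.array([model.sources[m].H_i for m in nodes])
    g2 = np.array([model.sources[m].gamma[1] for m in nodes])
    g4 = np.array([model.sources[m].gamma[3] for m in nodes])
    slope = np.array([model.sources[m].sigmoid_slope for m in nodes])

    if not np.all(np.isfinite(model.free_vector())):
        raise ValueError("model parameters must be finite")

    J = np.zeros((n * ns, n * ns))
    B = np.zeros((n * ns, n))
    Cout = np.zeros((n, n * ns))
    iv1, id1, iv2, id2, iv3e, id3e, iv3i, id3i = (np.arange(n) * ns + k for k in range(ns))

    # position/velocity chains and leaks
    for pos, vel, tau in ((iv1, id1, te), (iv2, id2, te), (iv3e, id3e, te), (iv3i, id3i, ti)):
        J[pos, vel] = 1.0
        J[vel, pos] += -1.0 / tau**2
        J[vel, vel] += -2.0 / tau

    # firing-rate couplings; presynaptic pyramidal potential p = v3e − v3i
    ke = (He / te)[:, None]
    for target_vel, W in ((id1, W1), (id2, W2), (id3e, W3)):
        C = ke * W * slope[None, :]
        J[np.ix_(target_vel, iv3e)] += C
        J[np.ix_(target_vel, iv3i)] -= C
    J[id3e, iv1] += (He / te) * g2 * slope
    J[id3i, iv2] += (Hi / ti) * g4 * slope

    B[id1, np.arange(n)] = (He / te) * np.exp(model.coupling.theta_C)
    Cout[np.arange(n), iv3e] = 1.0
    Cout[np.arange(n), iv3i] = -1.0
    return Linearization(J=J, B=B, Cout=Cout)


# ---------------------------------------------------------------------------
# predicted spectra and simulation

def observation_noise_spectrum(model: DCMModel, freqs: np.ndarray) -> np.ndarray:
    """G_n(f): channel-specific + common power-law observation noise."""
    f = np.asarray(freqs, dtype=float)[:, None, None]
    m = model.n_modes
    b1, b2 = model.nuisance.b
    c1, c2 = model.nuisance.c
    eye = np.eye(m)[None, :, :]
    ones = np.ones((m, m))[None, :, :]
    return np.exp(b1) * f ** (-np.exp(b2)) * eye + np.exp(c1) * f ** (-np.exp(c2)) * ones


def transfer_functions(model: DCMModel, freqs: np.ndarray,
                       lin: Linearization | None = None) -> np.ndarray:
    """T(f) = Cout·(2πif·I − J)⁻¹·B stacked over frequencies."""
    lin = lin or linearize(model)
    if not lin.stable:
        raise UnstableModelError("linearized network has unstable eigenmode")
    freqs = np.asarray(freqs, dtype=float)
    nstate = lin.J.shape[0]
    eye = np.eye(nstate)
    Bc = lin.B.astype(complex)
    out = np.empty((freqs.size, lin.Cout.shape[0], lin.B.shape[1]), dtype=complex)
    # chunked so dense frequency grids (long simulations) stay in memory
    for lo in range(0, freqs.size, 4096):
        chunk = freqs[lo:lo + 4096]
        M = 2j * np.pi * chunk[:, None, None] * eye[None, :, :] - lin.J[None, :, :]
        try:
            X = np.linalg.solve(M, np.broadcast_to(Bc, (chunk.size, *Bc.shape)))
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological
            raise RuntimeError(
                f"singular resolvent within band {chunk[0]}-{chunk[-1]} Hz") from exc
        out[lo:lo + 4096] = np.einsum("os,fsk->fok", lin.Cout, X)
    return out


def predict_csd(model: DCMModel, freqs: np.ndarray) -> CrossSpectra:
    """Model-predicted Hermitian cross-spectra at the requested frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    T = transfer_functions(model, freqs)
    gu = model.nuisance.innovations_power(freqs)            # (F, n_sources)
    H = np.einsum("ms,fsk->fmk", model.leadfield, T)        # lead-field-projected
    Gy = np.einsum("fmk,fk,fnk->fmn", H, gu, H.conj())
    Gy = Gy + observation_noise_spectrum(model, freqs)
    return CrossSpectra(freqs=freqs, G=hermitize(Gy))


def predict_csd_many(models: list[DCMModel], freqs: np.ndarray) -> np.ndarray:
    """Predicted cross-spectra for several models in one batched solve.

    All models must share graph shape and lead-field dimensions. Returns
    (n_models, n_freqs, m, m); raises :class:`UnstableModelError` naming
    the first unstable model index.
    """
    freqs = np.asarray(freqs, dtype=float)
    lins = []
    for i, mod in enumerate(models):
        lin = linearize(mod)
        if not lin.stable:
            raise UnstableModelError(f"model {i} in batch is unstable")
        lins.append(lin)
    P, F = len(models), freqs.size
    nstate = lins[0].J.shape[0]
    Js = np.stack([lin.J for lin in lins])                       # (P, n, n)
    omegas = 2j * np.pi * freqs
    M = (omegas[None, :, None, None] * np.eye(nstate)[None, None, :, :]
         - Js[:, None, :, :])
    B = np.stack([lin.B for lin in lins]).astype(complex)
    X = np.linalg.solve(M, np.broadcast_to(B[:, None], (P, F, *B.shape[1:])))
    T = np.einsum("os,pfsk->pfok", lins[0].Cout, X)
    gu = np.stack([mod.nuisance.innovations_power(freqs) for mod in models])
    H = np.einsum("pms,pfsk->pfmk",
                  np.stack([mod.leadfield for mod in models]), T)
    out = np.einsum("pfmk,pfk,pfnk->pfmn", H, gu, H.conj())
    m = models[0].n_modes
    b = np.array([mod.nuisance.b for mod in models])
    c = np.array([mod.nuisance.c for mod in models])
    fgrid = freqs[None, :, None, None]
    out += (np.exp(b[:, 0])[:, None, None, None]
            * fgrid ** (-np.exp(b[:, 1]))[:, None, None, None] * np.eye(m))
    out += (np.exp(c[:, 0])[:, None, None, None]
            * fgrid ** (-np.exp(c[:, 1]))[:, None, None, None] * np.ones((m, m)))
    return hermitize(out.reshape(P * F, m, m)).reshape(out.shape)


def simulate_timeseries(model: DCMModel, duration: float, rate: float,
                        seed: int | None = None,
                        innovation_scale: float = 1.0,
                        noise_scale: float = 1.0) -> ChannelTimeSeries:
    """Sample mode-level time series whose spectra match :func:`predict_csd`.

    The stationary solution of the linearized stochastic system is sampled
    directly in the frequency domain (circulant embedding): independent
    complex-Gaussian innovations with density g_u are pushed through the
    transfer function and lead field, and observation noise with density
    G_n is added, so the one-sided Welch spectrum of the output converges
    to the analytic prediction. Reproducible given ``seed``; with
    ``innovation_scale = noise_scale = 0`` the output is identically zero.
    """
    lin = linearize(model)
    if not lin.stable:
        raise UnstableModelError("refusing to simulate an unstable model")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    nf = freqs.size
    m, ns = model.n_modes, len(model.graph.nodes)

    # amplitude per rfft bin: E|Z_k|² = n·rate·S(f_k)/2 reproduces one-sided
    # density S under numpy's irfft normalization
    pos = freqs > 0
    T = transfer_functions(model, freqs[pos], lin)
    gu = model.nuisance.innovations_power(freqs[pos]) * innovation_scale**2
    scale_u = np.sqrt(n * rate * gu / 2.0)
    U = scale_u * (rng.standard_normal((nf - 1, ns)) + 1j * rng.standard_normal((nf - 1, ns))) / np.sqrt(2.0)
    Y = np.einsum("ms,fsk,fk->fm", model.leadfield, T, U)

    b1, b2 = model.nuisance.b
    c1, c2 = model.nuisance.c
    gb = np.exp(b1) * freqs[pos] ** (-np.exp(b2)) * noise_scale**2
    gc = np.exp(c1) * freqs[pos] ** (-np.exp(c2)) * noise_scale**2
    eps = (rng.standard_normal((nf - 1, m)) + 1j * rng.standard_normal((nf - 1, m))) / np.sqrt(2.0)
    eta = (rng.standard_normal(nf - 1) + 1j * rng.standard_normal(nf - 1)) / np.sqrt(2.0)
    Y = Y + np.sqrt(n * rate * gb / 4.0)[:, None] * eps
    Y = Y + (np.sqrt(n * rate * gc / 4.0) * eta)[:, None]

    Z = np.zeros((nf, m), dtype=complex)
    Z[1:] = Y
    if n % 2 == 0:      # Nyquist bin must be real for a real signal
        Z[-1] = Z[-1].real * np.sqrt(2.0)
    data = np.fft.irfft(Z, n=n, axis=0).T * 1.0
    return ChannelTimeSeries(data=data, rate=rate,
                             labels=tuple(f"mode{i+1}" for i in range(m)))
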