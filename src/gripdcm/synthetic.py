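"""Synthetic cohorts with the statistical structure the analysis assumes.

A cohort mirrors the study design: four age groups (n = 22, 19, 19, 28 by
default, 88 subjects), a per-subject precision-grip performance score with
group means improving into adulthood, and 14 extrinsic log-couplings
generated from the second-level GLM the group analysis assumes,

    θ_i = X_i β + ε_i,   ε_i ~ N(0, re_sd²·I),

with X built by the same design-matrix conventions the analysis uses.
Cross-spectra over the analysis band are generated from the neural-mass
model at the true couplings plus Hermitian observation noise; force
traces are the target line plus 1/f-shaped-plus-white noise scaled so the
behavioural scoring recovers the planted performance score exactly.

All randomness flows from the single config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .behavior import ForceTrace
from .neuralmass import (DCMModel, default_model, linearize, predict_csd,
                         simulate_timeseries)
from .peb import build_design_matrix
from .spectral import ChannelTimeSeries, CrossSpectra, hermitize

GROUP_LABELS = ("8-10", "12-14", "16-18", "20-30")
GROUP_PERF_MEANS = (0.30, 0.50, 0.60, 0.80)     # adults most precise
PERF_SD = 0.25
GROUP_AGE_MONTHS = (108.0, 156.0, 206.0, 301.0)
GROUP_AGE_SD = (7.0, 7.0, 7.0, 34.0)
TRACE_RATE = 100.0
TRACE_DURATION = 120.0
MVC_NEWTONS = 50.0


def edge_index(graph, kind: str, src: str, dst: str) -> int:
    for i, e in enumerate(graph.edges()):
        if e == (kind, src, dst):
            return i
    raise KeyError(f"no {kind} edge {src}->{dst}")


def default_effects() -> np.ndarray:
    """Planted second-level effects (regressors × 14 edges).

    Qualitatively mirrors the study findings: performance modulates the
    PMv↔IPL loop (±0.3), age group increases the SMA→IPL backward
    coupling, and interactions load on the PMv→DLPFC forward and SMA→M1
    backward couplings; commonalities are zero (couplings at baseline).
    """
    g = default_model().graph
    beta = np.zeros((4, 14))
    beta[1, edge_index(g, "backward", "PMv", "IPL")] = 0.3
    beta[1, edge_index(g, "forward", "IPL", "PMv")] = -0.3
    beta[2, edge_index(g, "backward", "SMA", "IPL")] = 0.3
    beta[3, edge_index(g, "forward", "PMv", "DLPFC")] = 0.3
    beta[3, edge_index(g, "backward", "SMA", "M1")] = 0.3
    return beta


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_per_group: tuple[int, ...] = (22, 19, 19, 28)
    effects: np.ndarray = field(default_factory=default_effects)
    re_sd: float = 0.05
    obs_noise: float = 0.005          # spectral noise, relative to rms |G|
    trace_noise: float = 0.5          # 1/f power fraction in the force-trace noise
    seed: int = 0

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.re_sd < 0 or self.obs_noise < 0:
            raise ValueError("noise scales must be nonnegative")
        if not 0.0 <= self.trace_noise <= 1.0:
            raise ValueError("trace_noise is the 1/f power fraction in [0, 1]")
        if len(self.n_per_group) < 2:
            raise ValueError("need at least two groups")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.n_per_group))


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    age_months: float
    performance: float
    theta: np.ndarray
    spectra: CrossSpectra | None = None
    trace: ForceTrace | None = None
    timeseries: ChannelTimeSeries | None = None


@dataclass
class SyntheticCohort:
    config: CohortConfig
    subjects: list[SyntheticSubject]
    model: DCMModel
    X: np.ndarray

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    @property
    def performance(self) -> np.ndarray:
        return np.array([s.performance for s in self.subjects])

    @property
    def theta(self) -> np.ndarray:
        return np.stack([s.theta for s in self.subjects])

    def to_frame(self):
        import pandas as pd
        edges = [f"{k}:{s}->{d}" for k, s, d in self.model.graph.edges()]
        recs = []
        for s in self.subjects:
            rec = {"subject": s.subject_id, "group": s.group,
                   "age_months": s.age_months, "performance": s.performance}
            rec.update(dict(zip(edges, s.theta)))
            recs.append(rec)
        return pd.DataFrame(recs)


def _cohort_truth(config: CohortConfig):
    """Deterministic group labels, performance, ages, design and couplings."""
    ss = np.random.SeedSequence(config.seed)
    r_perf, r_age, r_theta, r_spec, r_trace = [np.random.default_rng(c)
                                               for c in ss.spawn(5)]
    labels = GROUP_LABELS[:len(config.n_per_group)]
    groups = np.repeat(labels, config.n_per_group)
    gi = np.array([labels.index(g) for g in groups])
    perf = np.array(GROUP_PERF_MEANS)[gi] + r_perf.normal(0.0, PERF_SD, gi.size)
    ages = (np.array(GROUP_AGE_MONTHS)[gi]
            + r_age.normal(0.0, 1.0, gi.size) * np.array(GROUP_AGE_SD)[gi])
    X = build_design_matrix(perf, groups).X
    n_edges = config.effects.shape[1]
    theta = X @ config.effects + r_theta.normal(0.0, config.re_sd, (gi.size, n_edges))
    return groups, perf, ages, X, theta, r_spec, r_trace


def sample_subject_parameters(config: CohortConfig, subject_index: int) -> np.ndarray:
    """True couplings θ_i = X_i β + ε_i for one subject of the cohort."""
    theta = _cohort_truth(config)[4]
    return theta[subject_index]


def _force_trace(rng: np.random.Generator, score: float, pink_fraction: float) -> ForceTrace:
    """Target line plus colored noise whose RMSE reproduces exp(−score)."""
    n = int(TRACE_RATE * TRACE_DURATION)
    freqs = np.fft.rfftfreq(n, d=1.0 / TRACE_RATE)
    amp = np.zeros(freqs.size)
    amp[1:] = (np.sqrt(1.0 - pink_fraction)
               + np.sqrt(pink_fraction) / np.sqrt(freqs[1:]))
    z = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    noise = np.fft.irfft(z, n=n)
    noise -= noise.mean()
    rmse = float(np.exp(-score))
    noise *= rmse / np.sqrt(np.mean(noise**2))
    samples = 0.10 * MVC_NEWTONS + noise
    return ForceTrace(samples=samples, rate=TRACE_RATE, target=0.10, mvc=MVC_NEWTONS)


def generate_cohort(config: CohortConfig,
                    freqs: np.ndarray | None = None,
                    model: DCMModel | None = None,
                    with_timeseries: bool = False,
                    with_traces: bool = True) -> SyntheticCohort:
    """Generate a full cohort: couplings, cross-spectra and force traces.

    Spectra are the model prediction at each subject's true couplings plus
    Hermitian complex-Gaussian observation noise scaled to
    ``config.obs_noise`` × rms|G|. If a subject's sampled couplings leave
    the network unstable, the random effect is resampled (up to 10×).
    """
    freqs = np.arange(4.0, 49.0) if freqs is None else np.asarray(freqs, float)
    template = model if model is not None else default_model()
    groups, perf, ages, X, theta, r_spec, r_trace = _cohort_truth(config)

    subjects = []
    for i in range(config.n_subjects):
        th = theta[i]
        for attempt in range(10):
            m_i = template.with_couplings(th)
            if linearize(m_i).stable:
                break
            th = X[i] @ config.effects + r_spec.normal(0.0, config.re_sd, th.size)
        else:
            raise RuntimeError(f"subject {i}: no stable couplings after 10 resamples")
        theta[i] = th
        cs = predict_csd(m_i, freqs)
        if config.obs_noise > 0:
            scale = config.obs_noise * np.sqrt(np.mean(np.abs(cs.G) ** 2))
            E = scale * (r_spec.standard_normal(cs.G.shape)
                         + 1j * r_spec.standard_normal(cs.G.shape)) / np.sqrt(2.0)
            G = cs.G + hermitize(E)
        else:
            G = cs.G
        trace = _force_trace(r_trace, perf[i], config.trace_noise) if with_traces else None
        ts = None
        if with_timeseries:
            ts = simulate_timeseries(m_i, duration=120.0, rate=256.0,
                                     seed=int(r_spec.integers(2**31)))
        subjects.append(SyntheticSubject(
            subject_id=f"sub-{i:03d}", group=groups[i], age_months=float(ages[i]),
            performance=float(perf[i]), theta=th.copy(),
            spectra=CrossSpectra(freqs.copy(), G), trace=trace, timeseries=ts))
    return SyntheticCohort(config=config, subjects=subjects, model=template, X=X)


# ---------------------------------------------------------------------------
# serialization

def save_cohort(cohort: SyntheticCohort, directory) -> None:
    """Write config.yaml, subjects.csv and per-subject spectra/traces (HDF5)."""
    import h5py
    import yaml
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    cfg = asdict(cohort.config)
    cfg["effects"] = cohort.config.effects.tolist()
    cfg["n_per_group"] = list(cohort.config.n_per_group)
    (d / "config.yaml").write_text(yaml.safe_dump(cfg))
    cohort.to_frame().to_csv(d / "subjects.csv", index=False)
    with h5py.File(d / "subjects.h5", "w") as h5:
        for s in cohort.subjects:
            grp = h5.create_group(s.subject_id)
            grp.create_dataset("freqs", data=s.spectra.freqs)
            grp.create_dataset("G_real", data=s.spectra.G.real)
            grp.create_dataset("G_imag", data=s.spectra.G.imag)
            if s.trace is not None:
                tr = grp.create_dataset("trace", data=s.trace.samples)
                tr.attrs["rate"] = s.trace.rate
                tr.attrs["target"] = s.trace.target
                tr.attrs["mvc"] = s.trace.mvc


def load_cohort(directory) -> SyntheticCohort:
    import h5py
    import pandas as pd
    import yaml
    from pathlib import Path

    d = Path(directory)
    cfg_raw = yaml.safe_load((d / "config.yaml").read_text())
    cfg_raw["n_per_group"] = tuple(cfg_raw["n_per_group"])
    cfg_raw["effects"] = np.asarray(cfg_raw["effects"])
    config = CohortConfig(**cfg_raw)
    df = pd.read_csv(d / "subjects.csv")
    template = default_model()
    edges = [f"{k}:{s}->{dd}" for k, s, dd in template.graph.edges()]
    subjects = []
    with h5py.File(d / "subjects.h5", "r") as h5:
        for _, row in df.iterrows():
            grp = h5[row["subject"]]
            cs = CrossSpectra(np.asarray(grp["freqs"]),
                              np.asarray(grp["G_real"]) + 1j * np.asarray(grp["G_imag"]))
            trace = None
            if "trace" in grp:
                tr = grp["trace"]
                trace = ForceTrace(np.asarray(tr), rate=float(tr.attrs["rate"]),
                                   target=float(tr.attrs["target"]),
                                   mvc=float(tr.attrs["mvc"]))
            subjects.append(SyntheticSubject(
                subject_id=row["subject"], group=row["group"],
                age_months=float(row["age_months"]),
                performance=float(row["performance"]),
                theta=row[edges].to_numpy(dtype=float),
                spectra=cs, trace=trace))
    X = build_design_matrix(df["performance"].to_numpy(), df["group"].to_numpy()).X
    return SyntheticCohort(config=config, subjects=subjects, model=template, X=X)
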