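"""End-to-end orchestration of the analysis stages on one configuration.

behavior → (spectral) → subject-level inversion (full model, plus the
hidden-IPL control when model comparison is enabled) → RFX BMS → PEB with
greedy search and BMA → subject-estimate extraction → out-of-sample
prediction. The report is a JSON-serializable dict carrying every stage's
headline numbers plus provenance (config hash, seeds, package version);
rerunning with the same config and seed reproduces it except for the
timestamp.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field

from . import __version__
from .behavior import compute_precision_score, group_statistics
from .inversion import FitOptions, Hyperprior, fit_dcm
from .model_comparison import EvidenceTable, make_hidden_source_model, rfx_bms
from .peb import build_design_matrix, extract_subject_estimates, fit_peb, greedy_search_bma
from .prediction import FeatureTable, loocv_regression, qda_loocv
from .synthetic import CohortConfig, generate_cohort


class CohortSection(BaseModel):
    n_per_group: list[int] = [22, 19, 19, 28]
    re_sd: float = 0.05
    obs_noise: float = 0.005
    trace_noise: float = 0.5


class FitSection(BaseModel):
    max_iter: int = 32
    free: str = "couplings"           # "couplings" | "all"
    hE: float = 18.0
    hC: float = 1.0 / 128.0


class StageToggles(BaseModel):
    behavior: bool = True
    bms: bool = True
    peb: bool = True
    predict: bool = True


class PipelineConfig(BaseModel):
    """Validated single-document configuration of a full run."""

    seed: int = 0
    band: tuple[float, float] = (4.0, 48.0)
    n_modes: int = 4
    threshold: float = 0.95
    bms_samples: int = 100_000
    cohort: CohortSection = Field(default_factory=CohortSection)
    fit: FitSection = Field(default_factory=FitSection)
    stages: StageToggles = Field(default_factory=StageToggles)
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


class StageError(RuntimeError):
    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage, self.subject = stage, subject
        who = f" (subject {subject})" if subject else ""
        super().__init__(f"stage {stage!r}{who} failed: {cause}")


def _config_hash(cfg: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(cfg.model_dump(), sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; return (and optionally write) the report."""
    report: dict = {
        "provenance": {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                       "version": __version__, "timestamp": time.strftime("%FT%T")},
        "config": cfg.model_dump(),
    }
    freqs = np.arange(cfg.band[0], cfg.band[1] + 1.0)
    ccfg = CohortConfig(n_per_group=tuple(cfg.cohort.n_per_group),
                        re_sd=cfg.cohort.re_sd, obs_noise=cfg.cohort.obs_noise,
                        trace_noise=cfg.cohort.trace_noise, seed=cfg.seed)
    from .neuralmass import default_model
    cohort = generate_cohort(ccfg, freqs=freqs,
                             model=default_model(n_modes=cfg.n_modes))
    report["cohort"] = {"n_subjects": ccfg.n_subjects,
                        "groups": {g: int(n) for g, n in
                                   zip(("8-10", "12-14", "16-18", "20-30"),
                                       ccfg.n_per_group)}}

    # --- behavior ---------------------------------------------------------
    scores = None
    if cfg.stages.behavior:
        try:
            scores = [compute_precision_score(s.trace) for s in cohort.subjects]
            gs = group_statistics(scores, cohort.groups)
            report["behavior"] = {
                "F": gs.F, "df": list(gs.df), "p": gs.p,
                "pairwise": gs.pairwise.to_dict(orient="records"),
            }
        except Exception as exc:
            raise StageError("behavior", None, exc) from exc

    # --- subject-level inversion ------------------------------------------
    hyper = Hyperprior(hE=cfg.fit.hE, hC=cfg.fit.hC)
    opts = FitOptions(max_iter=cfg.fit.max_iter, free=cfg.fit.free)
    fits, fit_log = [], []
    for s in cohort.subjects:
        try:
            fr = fit_dcm(s.spectra, cohort.model, hyper=hyper, opts=opts)
        except Exception as exc:
            raise StageError("fit", s.subject_id, exc) from exc
        fits.append(fr)
        fit_log.append({"subject": s.subject_id, "F": fr.F, "r2": fr.r2,
                        "n_iter": fr.n_iter, "converged": fr.converged})
    report["fits"] = {"log": fit_log,
                      "mean_r2": float(np.mean([f.r2 for f in fits])),
                      "sd_r2": float(np.std([f.r2 for f in fits], ddof=1))}

    # --- model comparison -------------------------------------------------
    if cfg.stages.bms:
        hidden = make_hidden_source_model(cohort.model, "IPL")
        F_pairs = []
        for s, full_fit in zip(cohort.subjects, fits):
            try:
                hf = fit_dcm(s.spectra, hidden, hyper=hyper, opts=opts)
            except Exception as exc:
                raise StageError("bms", s.subject_id, exc) from exc
            F_pairs.append([full_fit.F, hf.F])
        bms = rfx_bms(EvidenceTable(np.array(F_pairs), ("full", "hidden-IPL")),
                      n_samples=cfg.bms_samples, seed=cfg.seed)
        report["bms"] = {"model_names": list(bms.model_names),
                         "expected_r": bms.expected_r.tolist(),
                         "xp": bms.xp.tolist(), "pxp": bms.pxp.tolist(),
                         "bor": bms.bor}

    # --- PEB + BMA --------------------------------------------------------
    estimates = None
    if cfg.stages.peb:
        try:
            perf = np.array([sc.score for sc in scores]) if scores is not None \
                else cohort.performance
            X = build_design_matrix(perf, cohort.groups)
            peb = fit_peb(fits, X)
            bma = greedy_search_bma(peb, threshold=cfg.threshold)
            estimates = extract_subject_estimates(peb, fits, bma)
        except Exception as exc:
            raise StageError("peb", None, exc) from exc
        report["peb"] = {"F": peb.F, "rfx_precision": peb.rfx_precision,
                         "effects": bma.table().to_dict(orient="records")}

    # --- prediction -------------------------------------------------------
    if cfg.stages.predict:
        if estimates is None:
            raise StageError("predict", None,
                             RuntimeError("prediction requires the peb stage"))
        try:
            table = FeatureTable(
                features=estimates,
                performance=cohort.performance,
                age_months=np.array([s.age_months for s in cohort.subjects]),
                age_group=cohort.groups,
                feature_names=tuple(f"{k}:{s}->{d}"
                                    for k, s, d in cohort.model.graph.edges()))
            reg_perf = loocv_regression(table, "performance")
            reg_age = loocv_regression(table, "age_months")
            cm = qda_loocv(table)
        except Exception as exc:
            raise StageError("predict", None, exc) from exc
        report["prediction"] = {
            "performance": {"rmse": reg_perf.rmse, "r2": reg_perf.r2},
            "age_months": {"rmse": reg_age.rmse, "r2": reg_age.r2},
            "qda": {"accuracy": cm.accuracy, "ci95": list(cm.ci95),
                    "p_vs_nir": cm.p_vs_nir,
                    "confusion": cm.counts.tolist(),
                    "labels": list(cm.labels)},
        }

    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
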