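"""End-to-end orchestration: simulate/extract -> invert -> PEB -> LOO.

A :class:`PipelineConfig` (YAML-serializable) toggles the stages; every
artifact is written with provenance (config hash, seed, package version).
The final report lists group-mean couplings and covariate effects, flags
effects whose posterior probability exceeds the configured cutoff (0.99 by
default — very strong evidence), labels connections with their pathway
role, and includes the leave-one-out predictive correlation when run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .extract import (extract_all_nodes, load_motion, load_nifti_mask,
                      load_nifti_volume)
from .invert import InversionSettings, PosteriorDensity, invert_subject
from .network import build_bg_network, default_priors, model_from_json, pathway_map
from .peb import (APATHY_COVARIATES, MOTOR_COVARIATES, build_design, loo_cv,
                  peb_fit, search_and_average)
from .simulate import canonical_scenario, null_scenario, write_cohort
from .spectra import SubjectTimeSeries, estimate_csd

logger = logging.getLogger("bgdcm.pipeline")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str, subject: str | None = None):
        self.stage = stage
        self.subject = subject
        msg = f"stage {stage!r} failed"
        if subject:
            msg += f" for subject {subject!r}"
        super().__init__(f"{msg}: {detail}")


@dataclass
class PipelineConfig:
    out_dir: str = "bgdcm_run"
    seed: int = 1
    scenario: str = "canonical"  # canonical | null
    n_subjects: int = 8
    design: str = "motor"  # motor | apathy | custom
    custom_covariates: list = field(default_factory=list)
    predict_column: str = "TMS"
    pp_cutoff: float = 0.99
    model_file: str | None = None
    stages: dict = field(default_factory=lambda: {
        "simulate": True, "extract": False, "invert": True,
        "peb": True, "loo": True,
    })
    with_volumes: bool = False
    data_dir: str | None = None  # existing cohort (skip simulate)
    clinical_file: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls(**(yaml.safe_load(Path(path).read_text()) or {}))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def content_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def covariates(self) -> list:
        if self.design == "motor":
            return list(MOTOR_COVARIATES)
        if self.design == "apathy":
            return list(APATHY_COVARIATES)
        return list(self.custom_covariates)


def _provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.content_hash(), "seed": config.seed,
            "version": __version__}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    config.to_yaml(out / "config.yaml")

    if config.model_file:
        if not Path(config.model_file).exists():
            raise StageError("setup", f"model file not found: {config.model_file}")
        spec, priors = model_from_json(config.model_file)
    else:
        spec = build_bg_network()
        priors = default_priors(spec)

    scenario = {"canonical": canonical_scenario, "null": null_scenario}.get(config.scenario)
    if scenario is None:
        raise StageError("setup", f"unknown scenario {config.scenario!r}")
    scenario = scenario()

    # --- simulate -------------------------------------------------------
    data_dir = Path(config.data_dir) if config.data_dir else out / "data"
    if config.stages.get("simulate", True):
        t0 = time.time()
        write_cohort(scenario, config.n_subjects, config.seed, data_dir,
                     volumes=config.with_volumes or config.stages.get("extract", False))
        logger.info("simulate: %d subjects in %.1fs", config.n_subjects, time.time() - t0)

    clinical_path = Path(config.clinical_file) if config.clinical_file else data_dir / "clinical.tsv"
    if not clinical_path.exists():
        raise StageError("peb", f"clinical table not found: {clinical_path}")
    clinical = pd.read_csv(clinical_path, sep="\t")
    subject_ids = clinical["subject_id"].tolist()

    # --- extract (or read node time series directly) --------------------
    series: dict[str, SubjectTimeSeries] = {}
    extraction_reports = {}
    for sid in subject_ids:
        if config.stages.get("extract", False):
            t0 = time.time()
            vdir = data_dir / sid
            try:
                vol = load_nifti_volume(vdir / "func.nii", tr=scenario.tr)
                masks = {n: load_nifti_mask(vdir / f"mask_{n}.nii", n)
                         for n in ("M1", "PUT", "STN", "THAL")}
                motion = load_motion(vdir / "motion.txt")
                nuis = np.loadtxt(vdir / "nuisance.txt")
                ts, rep = extract_all_nodes(vol, masks, motion, nuis, subject_id=sid)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError("extract", str(exc), subject=sid) from exc
            extraction_reports[sid] = rep
            series[sid] = ts
            logger.info("extract %s: %.1fs", sid, time.time() - t0)
        else:
            path = data_dir / f"{sid}_timeseries.tsv"
            if not path.exists():
                raise StageError("extract", f"time series not found: {path}", subject=sid)
            series[sid] = SubjectTimeSeries.from_tsv(path, subject_id=sid)

    # --- invert ---------------------------------------------------------
    posteriors: list[PosteriorDensity] = []
    post_dir = out / "posteriors"
    if config.stages.get("invert", True):
        post_dir.mkdir(exist_ok=True)
        settings = InversionSettings()
        for sid in subject_ids:
            t0 = time.time()
            try:
                csd = estimate_csd(series[sid])
                post = invert_subject(csd, priors, spec, settings, subject_id=sid)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError("invert", str(exc), subject=sid) from exc
            post.to_json(post_dir / f"{sid}.json")
            posteriors.append(post)
            logger.info("invert %s: F=%.1f ve=%.1f%% (%.1fs)", sid,
                        post.free_energy, post.variance_explained, time.time() - t0)

    report = {"provenance": _provenance(config), "stages_run": dict(config.stages)}
    if extraction_reports:
        report["extraction"] = extraction_reports
    if posteriors:
        report["variance_explained_mean"] = float(
            np.mean([p.variance_explained for p in posteriors]))

    # --- peb ------------------------------------------------------------
    if config.stages.get("peb", True) and posteriors:
        try:
            design = build_design(clinical, config.covariates())
            peb = peb_fit(posteriors, priors, design)
            bma = search_and_average(peb)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError("peb", str(exc)) from exc
        peb.to_json(out / "peb.json")
        bma.to_json(out / "bma.json")
        loo = None
        if config.stages.get("loo", True):
            try:
                loo = loo_cv(posteriors, priors, design, config.predict_column)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError("loo", str(exc)) from exc
            (out / "loo.json").write_text(json.dumps(loo.to_dict()))
        text, summary = render_report(peb.to_dict(), bma.to_dict(),
                                      loo.to_dict() if loo else None,
                                      pp_cutoff=config.pp_cutoff)
        summary["provenance"] = report["provenance"]
        (out / "report.txt").write_text(text)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        report["summary"] = summary

    report["elapsed_s"] = time.time() - t_start
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _pathway_label(param: str) -> str:
    pm = pathway_map(build_bg_network())
    if "->" in param:
        edge = tuple(param.split("->"))
        try:
            return pm.role_of(edge)
        except Exception:  # noqa: BLE001
            return "unmapped"
    if param.startswith("self_"):
        return f"self-connection ({param[5:]})"
    return ""


def render_report(peb_doc: dict, bma_doc: dict, loo_doc: dict | None = None,
                  pp_cutoff: float = 0.99) -> tuple[str, dict]:
    """Human-readable table + JSON summary of group results.

    Group means are in Hz; covariate effects in Hz per covariate unit; each
    row carries a 95% credible interval and the effect's posterior
    probability, with pathway labels on between-node connections.
    """
    for doc, keys in [(bma_doc, ("means", "variances", "pp",
                                 "covariate_labels", "param_labels"))]:
        for k in keys:
            if k not in doc:
                raise ValueError(f"malformed input: missing field {k!r}")
    means = np.asarray(bma_doc["means"], dtype=float)
    var = np.asarray(bma_doc["variances"], dtype=float)
    pp = np.asarray(bma_doc["pp"], dtype=float)
    covs = bma_doc["covariate_labels"]
    params = bma_doc["param_labels"]

    rows = []
    for ci, cov in enumerate(covs):
        for pi, par in enumerate(params):
            sd = float(np.sqrt(var[ci, pi]))
            rows.append({
                "covariate": cov, "connection": par,
                "pathway": _pathway_label(par),
                "estimate": float(means[ci, pi]),
                "ci95": [float(means[ci, pi] - 1.96 * sd),
                         float(means[ci, pi] + 1.96 * sd)],
                "pp": float(pp[ci, pi]),
                "units": "Hz" if cov == "mean" else "Hz per unit",
            })
    flagged = [r for r in rows if r["covariate"] != "mean" and r["pp"] > pp_cutoff
               and abs(r["estimate"]) > 0]

    lines = ["Group-level effective connectivity", "=" * 60]
    lines.append(f"{'covariate':<10}{'connection':<12}{'estimate':>10}"
                 f"{'95% CrI':>22}{'pp':>7}")
    for r in rows:
        if r["covariate"] == "mean" or r["pp"] > pp_cutoff:
            lines.append(f"{r['covariate']:<10}{r['connection']:<12}"
                         f"{r['estimate']:>10.3f}"
                         f"  [{r['ci95'][0]:>7.3f}, {r['ci95'][1]:>7.3f}]"
                         f"{r['pp']:>7.2f}  {r['pathway']}")
    lines.append("")
    lines.append(f"Effects with pp > {pp_cutoff}: "
                 + (", ".join(f"{r['covariate']} on {r['connection']}"
                              for r in flagged) if flagged else "none"))
    if loo_doc is not None:
        lines.append(f"Leave-one-out prediction: r = {loo_doc['r']:.3f}, "
                     f"one-tailed p = {loo_doc['p']:.3f}"
                     + ("  [flagged: constant predictions]"
                        if loo_doc.get("flagged") else ""))
    summary = {"rows": rows, "flagged": flagged, "pp_cutoff": pp_cutoff}
    if loo_doc is not None:
        summary["loo"] = {"r": loo_doc["r"], "p": loo_doc["p"],
                          "flagged": loo_doc.get("flagged", False)}
    return "\n".join(lines) + "\n", summary
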