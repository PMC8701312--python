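"""End-to-end analysis orchestration.

Runs simulate -> CT_spc + smoothing -> cohort statistics -> vertex-wise GLM
-> RFT cluster correction (optionally with the permutation oracle) ->
cluster-wise brain-behavior correlation -> expression decoding -> gene-set
enrichment from a single config, writing every artifact with a provenance
sidecar and collating the result tables into one machine-readable report.

Analysis stages receive only observables; the simulation truth channel is
written to a separate ``truth/`` directory and never read back.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, change, cohort_stats, decoding, glm, io, rft, synthetic

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "longicort-out"
    simulation: synthetic.SimulationConfig | None = None
    model: str = "group_model"          # preset name
    run_model_selection: bool = False
    fwhm: float = 10.0                  # mm, applied to CT_spc
    p_form: float = 0.05
    two_tailed: bool = True
    n_perm: int = 0                     # 0 disables the permutation oracle
    decoding_alpha: float = 0.05
    gene_set_paths: tuple = ()
    factor_map: dict | None = None      # RBS-R item -> factor; default synthetic map

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            rbsr = sim.pop("rbsr", None)
            expr = sim.pop("expression", None)
            simcfg = synthetic.SimulationConfig(**sim)
            if rbsr:
                simcfg.rbsr = synthetic.RbsrSimConfig(**rbsr)
            if expr:
                simcfg.expression = synthetic.ExpressionSimConfig(**expr)
            cfg.simulation = simcfg
        for p in cfg.gene_set_paths:
            if not Path(p).exists():
                raise FileNotFoundError(f"gene set file not found: {p}")
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the report dict (also written to JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    stage = "setup"
    try:
        stage = "simulate"
        sim = config.simulation or synthetic.SimulationConfig(seed=config.seed)
        sim.seed = sim.seed or config.seed
        cohort = synthetic.simulate_cohort(sim)
        mesh = cohort.mesh
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        np.savetxt(truth_dir / "planted_labels.csv",
                   cohort.truth["planted_labels"], fmt="%d")
        report["stages"]["simulate"] = {
            "n_subjects": len(cohort.subjects), "n_vertices": mesh.n_vertices,
            "seed": sim.seed}

        stage = "ctspc"
        isi = cohort.isi
        ctspc = change.ctspc_matrix(cohort.ct_t1, cohort.ct_t2, isi)
        ctspc_sm = change.smooth(ctspc, mesh, config.fwhm)
        smooth_info = change.smoothing_info(mesh, config.fwhm)
        mean_ct_t1, area_m2 = change.total_brain_summaries(cohort.ct_t1, mesh)
        report["stages"]["ctspc"] = {
            "smoothing": smooth_info,
            "mean_ct_t1_mm": float(np.mean(mean_ct_t1)),
            "total_surface_area_m2": area_m2}

        stage = "cohort_stats"
        factor_map = {int(k): v for k, v in config.factor_map.items()} \
            if config.factor_map else synthetic.DEFAULT_FACTOR_MAP
        table1 = cohort_stats.group_comparison_table(cohort.subjects, factor_map,
                                                     seed=config.seed)
        table1.to_csv(out / "group_comparison.tsv", sep="\t", index=False)
        io.write_sidecar(out / "group_comparison.tsv", stage="cohort_stats",
                         parameters={"welch": True, "yates": True}, seed=config.seed)
        report["stages"]["cohort_stats"] = table1.to_dict(orient="records")

        stage = "glm"
        frame = cohort.subjects.to_frame()
        t1m = cohort_stats.pmm_impute(cohort.subjects.rbsr_matrix(1), seed=config.seed)
        t2m = cohort_stats.pmm_impute(cohort.subjects.rbsr_matrix(2), seed=config.seed + 1)
        scores = cohort_stats.score_rbsr(t1m, t2m, factor_map)
        frame["delta_rbsr"] = scores.delta_total
        design = glm.build_design(frame, config.model)
        selection = None
        if config.run_model_selection:
            seq = [glm.build_design(frame, m) for m in
                   ("group_model", "rbsr_model", "rbsr_interaction_model")]
            selection = glm.stepup_model_selection(ctspc_sm, seq)
            design = selection.selected
        contrast = "group" if "group" in design.names else design.names[1]
        fit = glm.fit_glm(ctspc_sm, design, contrast)
        report["stages"]["glm"] = {
            "model": config.model, "dof": fit.dof, "columns": list(design.names),
            "selection": None if selection is None else [
                {"added": list(s.added), "f": s.f, "p": s.p, "admitted": s.admitted}
                for s in selection.steps]}

        stage = "cluster_correct"
        if config.n_perm > 0:
            clusters, smoothness = rft.permutation_cluster_test(
                ctspc_sm, design, contrast, mesh, p_form=config.p_form,
                n_perm=config.n_perm, seed=config.seed, two_tailed=config.two_tailed)
            perm_p = {c.id: c.p for c in clusters}
            smoothness = rft.estimate_smoothness(fit.residuals, mesh, fit.dof)
            u = rft.forming_threshold(config.p_form, fit.dof, config.two_tailed)
            for c in clusters:
                c.p = rft.cluster_p_rft(c.resel_extent, smoothness, fit.dof, u,
                                        config.two_tailed)
        else:
            clusters = rft.cluster_correct(fit.tmap, fit.residuals, mesh, fit.dof,
                                           config.p_form, config.two_tailed)
            perm_p = {}
        cluster_table = pd.DataFrame([
            {"id": c.id, "sign": c.sign, "vertices": c.n_vertices,
             "area_mm2": c.area_mm2, "resels": c.resel_extent,
             "peak_t": c.peak_t, "peak_vertex": c.peak_vertex, "p": c.p,
             **({"p_perm": perm_p[c.id]} if c.id in perm_p else {})}
            for c in clusters])
        cluster_table.to_csv(out / "clusters.tsv", sep="\t", index=False)
        io.write_sidecar(out / "clusters.tsv", stage="cluster_correct",
                         parameters={"p_form": config.p_form,
                                     "two_tailed": config.two_tailed},
                         seed=config.seed)
        report["stages"]["clusters"] = cluster_table.to_dict(orient="records")

        stage = "brain_behavior"
        significant = [c for c in clusters if c.p < 0.05]
        if significant:
            feats = behavior.extract_cluster_means(
                ctspc_sm, significant,
                subject_ids=[s.subject_id for s in cohort.subjects])
            measures = pd.DataFrame({
                "rbsr_total_t1": scores.total_t1,
                "delta_rbsr_total": scores.delta_total})
            corr = behavior.correlate_with_fdr(feats, measures)
            corr.to_csv(out / "brain_behavior.tsv", sep="\t", index=False)
            report["stages"]["brain_behavior"] = corr.to_dict(orient="records")
        else:
            report["stages"]["brain_behavior"] = []

        stage = "decode"
        expr, _planted = synthetic.simulate_expression(
            mesh, fit.tmap, sim.expression, seed=config.seed)
        dec = decoding.decode(fit.tmap, expr, alpha=config.decoding_alpha)
        gene_sets = []
        for p in config.gene_set_paths:
            gene_sets.extend(io.read_gene_sets(p))
        if not gene_sets:
            top = dec.table.head(30)["gene"].tolist()
            gene_sets = [io.GeneSet("top-decoded-synthetic", tuple(top),
                                    "synthetic demo set")]
        enr = decoding.enrich(dec.candidates, gene_sets, expr.universe_size)
        enr.table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["stages"]["decode"] = {
            "n_candidates": len(dec.candidates), "alpha": dec.alpha,
            "universe": expr.universe_size}
        report["stages"]["enrichment"] = enr.table.to_dict(orient="records")

    except Exception as exc:
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "error.json").write_text(json.dumps(
            {"stage": stage, "error": str(exc)}, indent=1))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)
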