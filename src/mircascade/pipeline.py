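"""End-to-end orchestration of the discovery cascade.

Stage order follows the discovery funnel: detection -> segmental
fold-change -> exponential trajectory -> interaction restriction ->
iFC scoring, with optional cross-dataset concordance and random-forest
stage evaluation.  :func:`run_cascade` is the in-memory core;
:func:`run_all` wraps it with a YAML config, stage TSV outputs, a GraphML
network and a machine-readable JSON run report whose funnel counts are
non-increasing along the cascade for each transcript kind.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crossval import concordance, grouping_diagnostics
from .datasets import ExpressionDataset, TimeProfile, quantile_normalize, read_expression, to_profiles
from .filters import (
    ExpFitResult,
    SegmentScheme,
    SegmentalCall,
    detection_filter,
    fit_exp2,
    segmental_fold_change,
)
from .ifc import IfcScore, score_pairs, write_scores
from .interactions import InteractionPair, export_network, load_interactions, restrict_and_filter
from .rf_eval import compare_stages, evaluate_stage

__all__ = ["PipelineParams", "CascadeResult", "RunReport", "run_cascade", "run_all"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Every tunable of the cascade in one place (defaults = study settings)."""

    segments: SegmentScheme
    min_timepoints: int = 6
    detect_thr: float | None = None  # None -> 10th percentile of each matrix
    low_thr: float = 0.8
    high_thr: float = 1.2
    fc_strategy: str = "endpoints"
    skip_segmental: bool = False
    r_threshold: float = 0.7
    n_starts: int = 8
    goodness: str = "r"
    min_confidence: str = "high"
    r_cut: float = -0.5
    p_cut: float = 1.0
    apply_quantile_norm: bool = False
    seed: int = 0


@dataclass
class CascadeResult:
    """All intermediate and final products of one cascade run."""

    genes_detected: ExpressionDataset
    mirnas_detected: ExpressionDataset
    gene_calls: list[SegmentalCall]
    mirna_calls: list[SegmentalCall]
    gene_segmental_ids: list[str]
    mirna_segmental_ids: list[str]
    gene_fits: list[ExpFitResult]
    mirna_fits: list[ExpFitResult]
    gene_exp_ids: list[str]
    mirna_exp_ids: list[str]
    restricted_pairs: list[InteractionPair]
    scores: list[IfcScore]
    funnel: dict[str, dict[str, int]]

    @property
    def high_stringency(self) -> list[IfcScore]:
        return [s for s in self.scores if s.high_stringency]

    def profiles(self, kind: str) -> dict[str, TimeProfile]:
        ds = self.genes_detected if kind == "gene" else self.mirnas_detected
        return {p.transcript_id: p for p in to_profiles(ds)}


@dataclass
class RunReport:
    """Machine-readable summary of one :func:`run_all` invocation."""

    config: dict
    funnel: dict[str, dict[str, int]]
    timings_s: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def _informative_ids(calls: list[SegmentalCall], order: list[str]) -> list[str]:
    """Union of per-segment informative sets, preserving input transcript order."""
    informative = {c.transcript_id for c in calls if c.informative}
    return [t for t in order if t in informative]


def _whole_course_fold_changes(ds: ExpressionDataset) -> dict[str, float]:
    out = {}
    for prof in to_profiles(ds):
        out[prof.transcript_id] = float(2.0 ** (prof.mean_log2[-1] - prof.mean_log2[0]))
    return out


def run_cascade(
    genes: ExpressionDataset,
    mirnas: ExpressionDataset,
    pairs: list[InteractionPair],
    params: PipelineParams,
) -> CascadeResult:
    """Run detection -> segmental -> exponential -> restriction -> iFC in memory."""
    if params.apply_quantile_norm:
        genes = quantile_normalize(genes)
        mirnas = quantile_normalize(mirnas)

    funnel: dict[str, dict[str, int]] = {"gene": {}, "mirna": {}, "pairs": {}}
    funnel["gene"]["input"] = genes.n_transcripts
    funnel["mirna"]["input"] = mirnas.n_transcripts
    funnel["pairs"]["input"] = len(pairs)

    genes_det = detection_filter(genes, params.min_timepoints, params.detect_thr)
    mirnas_det = detection_filter(mirnas, params.min_timepoints, params.detect_thr)
    funnel["gene"]["detected"] = genes_det.n_transcripts
    funnel["mirna"]["detected"] = mirnas_det.n_transcripts

    gene_profiles = to_profiles(genes_det)
    mirna_profiles = to_profiles(mirnas_det)

    if params.skip_segmental:
        gene_calls: list[SegmentalCall] = []
        mirna_calls: list[SegmentalCall] = []
        gene_seg_ids = [p.transcript_id for p in gene_profiles]
        mirna_seg_ids = [p.transcript_id for p in mirna_profiles]
    else:
        gene_calls = segmental_fold_change(
            gene_profiles, params.segments, params.low_thr, params.high_thr, params.fc_strategy
        )
        mirna_calls = segmental_fold_change(
            mirna_profiles, params.segments, params.low_thr, params.high_thr, params.fc_strategy
        )
        gene_seg_ids = _informative_ids(gene_calls, genes_det.transcript_ids)
        mirna_seg_ids = _informative_ids(mirna_calls, mirnas_det.transcript_ids)
    funnel["gene"]["segmental"] = len(gene_seg_ids)
    funnel["mirna"]["segmental"] = len(mirna_seg_ids)

    prof_by_id_g = {p.transcript_id: p for p in gene_profiles}
    prof_by_id_m = {p.transcript_id: p for p in mirna_profiles}
    gene_fits = [
        fit_exp2(prof_by_id_g[t], params.r_threshold, params.n_starts, params.goodness)
        for t in gene_seg_ids
    ]
    mirna_fits = [
        fit_exp2(prof_by_id_m[t], params.r_threshold, params.n_starts, params.goodness)
        for t in mirna_seg_ids
    ]
    gene_exp_ids = [f.transcript_id for f in gene_fits if f.passed]
    mirna_exp_ids = [f.transcript_id for f in mirna_fits if f.passed]
    funnel["gene"]["exponential"] = len(gene_exp_ids)
    funnel["mirna"]["exponential"] = len(mirna_exp_ids)

    restricted = restrict_and_filter(pairs, gene_exp_ids, mirna_exp_ids, params.min_confidence)
    funnel["pairs"]["restricted"] = len(restricted)

    scores = score_pairs(
        restricted, prof_by_id_g, prof_by_id_m, r_cut=params.r_cut, p_cut=params.p_cut
    )
    funnel["pairs"]["scored"] = len(scores)
    funnel["pairs"]["high_stringency"] = sum(s.high_stringency for s in scores)

    funnel["gene"]["in_network"] = len({s.gene_id for s in scores})
    funnel["mirna"]["in_network"] = len({s.mirna_id for s in scores})

    return CascadeResult(
        genes_detected=genes_det,
        mirnas_detected=mirnas_det,
        gene_calls=gene_calls,
        mirna_calls=mirna_calls,
        gene_segmental_ids=gene_seg_ids,
        mirna_segmental_ids=mirna_seg_ids,
        gene_fits=gene_fits,
        mirna_fits=mirna_fits,
        gene_exp_ids=gene_exp_ids,
        mirna_exp_ids=mirna_exp_ids,
        restricted_pairs=restricted,
        scores=scores,
        funnel=funnel,
    )


# -- file-based orchestration --------------------------------------------------


def _load_scheme(raw: list[dict]) -> SegmentScheme:
    return SegmentScheme(tuple((d["name"], float(d["lo"]), float(d["hi"])) for d in raw))


def _params_from_config(cfg: dict) -> PipelineParams:
    det = cfg.get("detection", {})
    seg = cfg.get("segmental", {})
    exp = cfg.get("exponential", {})
    inter = cfg.get("interactions_filter", {})
    ifc_cfg = cfg.get("ifc", {})
    return PipelineParams(
        segments=_load_scheme(cfg["segments"]),
        min_timepoints=int(det.get("min_timepoints", 6)),
        detect_thr=det.get("detect_thr"),
        low_thr=float(seg.get("low_thr", 0.8)),
        high_thr=float(seg.get("high_thr", 1.2)),
        fc_strategy=seg.get("strategy", "endpoints"),
        skip_segmental=bool(seg.get("skip", False)),
        r_threshold=float(exp.get("r_threshold", 0.7)),
        n_starts=int(exp.get("n_starts", 8)),
        goodness=exp.get("goodness", "r"),
        min_confidence=inter.get("min_confidence", "high"),
        r_cut=float(ifc_cfg.get("r_cut", -0.5)),
        p_cut=float(ifc_cfg.get("p_cut", 1.0)),
        apply_quantile_norm=bool(cfg.get("quantile_normalize", False)),
        seed=int(cfg.get("seed", 0)),
    )


def _calls_frame(calls: list[SegmentalCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [c.transcript_id for c in calls],
            "segment": [c.segment_name for c in calls],
            "fold_change": [c.fold_change for c in calls],
            "direction": [c.direction for c in calls],
            "informative": [c.informative for c in calls],
        }
    )


def _fits_frame(fits: list[ExpFitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [f.transcript_id for f in fits],
            "a": [f.a for f in fits],
            "b": [f.b for f in fits],
            "c": [f.c for f in fits],
            "d": [f.d for f in fits],
            "r_goodness": [f.r_goodness for f in fits],
            "passed": [f.passed for f in fits],
        }
    )


def run_all(config_path: str | Path) -> RunReport:
    """Execute the full cascade from a YAML config; write stage outputs + report.

    Any stage error aborts with the stage name and the offending item in the
    message; outputs written so far are kept and a ``<out_dir>/.partial``
    marker is left behind.
    """
    cfg = yaml.safe_load(Path(config_path).read_text())

    # startup validation before any computation
    for key in ("genes", "mirnas", "interactions", "out_dir", "segments"):
        if key not in cfg:
            raise ValueError(f"config missing required key {key!r}")
    for kind in ("genes", "mirnas"):
        for sub in ("matrix", "meta"):
            p = Path(cfg[kind][sub])
            if not p.exists():
                raise FileNotFoundError(f"{kind} {sub} file not found: {p}")
    if not Path(cfg["interactions"]).exists():
        raise FileNotFoundError(f"interaction table not found: {cfg['interactions']}")

    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    partial_marker = out_dir / ".partial"
    partial_marker.write_text("run in progress\n")

    params = _params_from_config(cfg)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    stage = "load"
    try:
        t0 = time.perf_counter()
        genes = read_expression(cfg["genes"]["matrix"], cfg["genes"]["meta"], "gene")
        mirnas = read_expression(cfg["mirnas"]["matrix"], cfg["mirnas"]["meta"], "mirna")
        pairs = load_interactions(cfg["interactions"])
        timings["load"] = time.perf_counter() - t0

        stage = "cascade"
        t0 = time.perf_counter()
        result = run_cascade(genes, mirnas, pairs, params)
        timings["cascade"] = time.perf_counter() - t0

        stage = "write_outputs"
        t0 = time.perf_counter()
        if not result.high_stringency:
            logger.warning("high-stringency pair set is empty under the configured thresholds")
        for name, frame in (
            ("gene_segmental_calls", _calls_frame(result.gene_calls)),
            ("mirna_segmental_calls", _calls_frame(result.mirna_calls)),
            ("gene_exp_fits", _fits_frame(result.gene_fits)),
            ("mirna_exp_fits", _fits_frame(result.mirna_fits)),
        ):
            path = out_dir / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            outputs[name] = str(path)
        ranked = out_dir / "ranked_pairs.tsv"
        write_scores(result.scores, ranked)
        outputs["ranked_pairs"] = str(ranked)

        fold_changes = {
            **_whole_course_fold_changes(result.genes_detected),
            **_whole_course_fold_changes(result.mirnas_detected),
        }
        graph_path = out_dir / "network.graphml"
        export_network(result.restricted_pairs, fold_changes, graph_path)
        outputs["network"] = str(graph_path)
        timings["write_outputs"] = time.perf_counter() - t0

        if cfg.get("externals"):
            stage = "concordance"
            t0 = time.perf_counter()
            by_kind = {"gene": [], "mirna": []}
            for ext in cfg["externals"]:
                by_kind[ext["kind"]].append(
                    read_expression(ext["matrix"], ext["meta"], ext["kind"])
                )
            rows = []
            for kind, ref, ids in (
                ("gene", result.genes_detected, sorted({s.gene_id for s in result.scores})),
                ("mirna", result.mirnas_detected, sorted({s.mirna_id for s in result.scores})),
            ):
                if by_kind[kind] and ids:
                    for rec in concordance(ref, by_kind[kind], ids):
                        rows.append({"kind": kind, **dataclasses.asdict(rec)})
            conc_path = out_dir / "concordance.tsv"
            pd.DataFrame(rows).to_csv(conc_path, sep="\t", index=False)
            outputs["concordance"] = str(conc_path)
            timings["concordance"] = time.perf_counter() - t0

        if cfg.get("rf_eval", {}).get("enabled", False):
            stage = "rf_eval"
            t0 = time.perf_counter()
            rf_cfg = cfg["rf_eval"]
            stages = [
                ("segmental", result.gene_segmental_ids),
                ("exponential", result.gene_exp_ids),
                ("ifc_high_stringency", sorted({s.gene_id for s in result.high_stringency})),
            ]
            evals = []
            for name, ids in stages:
                if ids:
                    ev = evaluate_stage(
                        result.genes_detected,
                        ids,
                        stage_name=name,
                        n_folds=int(rf_cfg.get("n_folds", 10)),
                        n_trees=int(rf_cfg.get("n_trees", 500)),
                        seed=params.seed,
                    )
                    evals.append(ev)
                    roc_path = out_dir / f"roc_{name}.tsv"
                    pd.DataFrame(ev.roc_points, columns=["fpr", "tpr"]).to_csv(
                        roc_path, sep="\t", index=False
                    )
                    outputs[f"roc_{name}"] = str(roc_path)
            if len(evals) >= 2:
                cmp_path = out_dir / "stage_comparison.tsv"
                compare_stages(evals).to_csv(cmp_path, sep="\t", index=False)
                outputs["stage_comparison"] = str(cmp_path)
            timings["rf_eval"] = time.perf_counter() - t0

        if cfg.get("diagnostics", {}).get("enabled", False):
            stage = "diagnostics"
            t0 = time.perf_counter()
            sig_genes = sorted({s.gene_id for s in result.high_stringency})
            if len(sig_genes) >= 2:
                diag = grouping_diagnostics(result.genes_detected, sig_genes)
                pca_path = out_dir / "pca_scores.tsv"
                diag.pca_scores.to_csv(pca_path, sep="\t")
                outputs["pca_scores"] = str(pca_path)
                nwk_path = out_dir / "dendrogram.nwk"
                nwk_path.write_text(diag.newick + "\n")
                outputs["dendrogram"] = str(nwk_path)
            timings["diagnostics"] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted in stage {stage!r}: {exc}") from exc

    report = RunReport(
        config=cfg, funnel=result.funnel, timings_s=timings, outputs=outputs, seed=params.seed
    )
    report_path = out_dir / "report.json"
    report.to_json(report_path)
    report.outputs["report"] = str(report_path)
    report.to_json(report_path)
    partial_marker.unlink(missing_ok=True)
    return report
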