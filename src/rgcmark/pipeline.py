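"""Pipeline orchestration: qc -> variance filter -> clustering -> marker screens.

One configured run covers either a synthetic dataset (generated in-process
from a SimConfig) or matrices/annotations read from disk.  Every stage's
output lands in a report bundle whose files are byte-reproducible given the
same config and seed; the manifest records every decision knob in force.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .matrixio import (
    CellAnnotation,
    ExpressionMatrix,
    ProbeAnnotation,
    annotations_to_frame,
    group_map,
    read_annotations,
    read_matrix,
    read_probe_map,
)
from .qc import QCRule, library_qc
from .variance import (
    DEFAULT_SD_THRESHOLD,
    SDMixtureResult,
    dual_sd_filter,
    fit_sd_mixture,
    per_group_sd,
    suggest_threshold,
    FilterResult,
)
from .cluster import (
    ClusterAssignment,
    Dendrogram,
    average_linkage,
    correlation_distance,
    cluster_enriched_genes,
    cut_tree,
)
from .markers import (
    DEFAULT_MIN_CELLS,
    DEFAULT_R_THRESHOLD,
    CorrelateList,
    prevalence_markers,
    seed_correlates,
)
from .simulate import SimConfig, SimTruth, generate_dataset

logger = logging.getLogger("rgcmark")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of (input paths, sim) must be set."""

    matrix_path: Optional[str] = None
    annotations_path: Optional[str] = None
    probe_map_path: Optional[str] = None
    sim: Optional[SimConfig] = None
    detection_threshold: float = 6.0
    sd_threshold: float = DEFAULT_SD_THRESHOLD
    strict_sd_filter: bool = True
    k: int = 4
    r_threshold: float = DEFAULT_R_THRESHOLD
    min_cells: int = DEFAULT_MIN_CELLS
    min_in_prev: float = 0.75
    max_out_prev: float = 0.25
    seed_genes: Sequence[str] = ()
    correlate_substrate: str = "retained"  # or "all"
    qc_required: Sequence[str] = ("Sncg",)
    qc_excluded: Sequence[str] = ("Rho", "Glul")
    run_qc: bool = True
    min_enriched_cluster_size: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = self.matrix_path is not None
        has_sim = self.sim is not None
        if has_paths == has_sim:
            raise ValueError("exactly one of (matrix_path, sim) must be set")
        if self.correlate_substrate not in ("retained", "all"):
            raise ValueError("correlate_substrate must be 'retained' or 'all'")
        for name, v, lo, hi in (
            ("sd_threshold", self.sd_threshold, 0.0, np.inf),
            ("r_threshold", self.r_threshold, -1.0, 1.0),
            ("min_in_prev", self.min_in_prev, 0.0, 1.0),
            ("max_out_prev", self.max_out_prev, 0.0, 1.0),
        ):
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    matrix: ExpressionMatrix
    annotations: list[CellAnnotation]
    probe_map: Optional[ProbeAnnotation]
    truth: Optional[SimTruth]
    qc_report: Optional[pd.DataFrame]
    sd_table: pd.DataFrame
    mixture_target: SDMixtureResult
    mixture_comparison: SDMixtureResult
    filter_result: FilterResult
    dendrogram: Dendrogram
    assignment: ClusterAssignment
    enriched: dict[int, pd.DataFrame]
    marker_report: pd.DataFrame
    correlates: dict[str, CorrelateList]
    manifest: dict

    def write_bundle(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.qc_report is not None:
            self.qc_report.to_csv(out / "qc_report.tsv", sep="\t")
        self.filter_result.to_frame(self.sd_table).to_csv(
            out / "sd_filter.tsv", sep="\t"
        )
        with open(out / "sd_mixture.json", "w") as fh:
            json.dump(
                {
                    "target": self.mixture_target.to_dict(),
                    "comparison": self.mixture_comparison.to_dict(),
                    "suggested_threshold_target": suggest_threshold(self.mixture_target),
                    "suggested_threshold_comparison": suggest_threshold(
                        self.mixture_comparison
                    ),
                },
                fh,
                indent=2,
            )
        with open(out / "tree.nwk", "w") as fh:
            fh.write(self.dendrogram.to_newick() + "\n")
        self.assignment.to_frame().to_csv(out / "clusters.tsv", sep="\t")
        for label, table in self.enriched.items():
            table.to_csv(out / f"enriched_cluster{label}.tsv", sep="\t", index=False)
        self.marker_report.to_csv(out / "prevalence_markers.tsv", sep="\t", index=False)
        for seed_gene, clist in self.correlates.items():
            clist.entries.to_csv(
                out / f"correlates_{seed_gene}.tsv", sep="\t", index=False
            )
            with open(out / f"correlates_{seed_gene}.json", "w") as fh:
                json.dump(clist.to_dict(), fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        return out


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # propagate with stage context
                raise PipelineError(name, str(exc)) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute qc -> filter -> cluster -> screens and return the full bundle."""
    cfg = config

    # ---- inputs --------------------------------------------------------------
    truth: Optional[SimTruth] = None
    if cfg.sim is not None:
        sim_cfg = cfg.sim
        if sim_cfg.seed != cfg.seed:
            sim_cfg = SimConfig(**{**asdict_simconfig(sim_cfg), "seed": cfg.seed})
        matrix, annotations, truth, probe_map = generate_dataset(sim_cfg)
        logger.info("simulate: %d probes x %d cells", *matrix.shape)
    else:
        matrix = read_matrix(cfg.matrix_path)
        annotations = read_annotations(cfg.annotations_path)
        probe_map = (
            read_probe_map(cfg.probe_map_path) if cfg.probe_map_path else None
        )
    groups = group_map(annotations)
    target_cells = [c for c in matrix.cell_ids if groups.get(c) == "target"]

    # ---- qc ------------------------------------------------------------------
    qc_report = None
    if cfg.run_qc and probe_map is not None:
        rule = QCRule(
            tuple(cfg.qc_required), tuple(cfg.qc_excluded), cfg.detection_threshold
        )
        qc_report = _stage("qc")(library_qc)(matrix, probe_map, rule)
        n_fail = int((~qc_report.loc[target_cells, "qc_pass"]).sum())
        logger.info(
            "qc: %d/%d target cells pass (%d flagged; no cells dropped)",
            len(target_cells) - n_fail,
            len(target_cells),
            n_fail,
        )

    # ---- variance filter -----------------------------------------------------
    sd_table = _stage("filter")(per_group_sd)(matrix, groups)
    fit = _stage("filter")(fit_sd_mixture)
    mixture_target = fit(sd_table["sd_target"].to_numpy(), seed=cfg.seed)
    mixture_comparison = fit(sd_table["sd_comparison"].to_numpy(), seed=cfg.seed)
    filter_result = _stage("filter")(dual_sd_filter)(
        sd_table, cfg.sd_threshold, cfg.strict_sd_filter
    )
    logger.info(
        "filter: %d of %d probes retained at SD > %.3g (both groups)",
        filter_result.n_retained,
        filter_result.n_input,
        cfg.sd_threshold,
    )

    # ---- clustering ----------------------------------------------------------
    distances = _stage("cluster")(correlation_distance)(
        matrix, filter_result.retained_probe_ids
    )
    dendrogram = _stage("cluster")(average_linkage)(distances)
    assignment = _stage("cluster")(cut_tree)(dendrogram, cfg.k)
    logger.info("cluster: k=%d cut, sizes %s", cfg.k, assignment.sizes())

    # ---- screens -------------------------------------------------------------
    target_set = set(target_cells)
    enriched: dict[int, pd.DataFrame] = {}
    screen = _stage("screens")(cluster_enriched_genes)
    for label in range(1, cfg.k + 1):
        cells = assignment.cells_in(label)
        if len(cells) < cfg.min_enriched_cluster_size:
            continue
        if target_set and not any(c in target_set for c in cells):
            continue  # comparison-only cluster: not a marker target
        enriched[label] = screen(
            matrix,
            assignment,
            label,
            cfg.detection_threshold,
            cfg.min_in_prev,
            cfg.max_out_prev,
            probe_map,
        )
    marker_cells = target_cells or matrix.cell_ids
    marker_report = _stage("screens")(prevalence_markers)(
        matrix, marker_cells, cfg.detection_threshold, cfg.min_cells, probe_map
    )
    correlates: dict[str, CorrelateList] = {}
    if cfg.correlate_substrate == "retained":
        corr_matrix = matrix.subset(probes=filter_result.retained_probe_ids)
    else:
        corr_matrix = matrix
    seed_genes = list(cfg.seed_genes)
    for gene in seed_genes:
        correlates[gene] = _stage("screens")(seed_correlates)(
            corr_matrix, gene, cfg.r_threshold, None, probe_map
        )

    manifest = build_manifest(cfg, matrix, filter_result, assignment)
    return PipelineResult(
        config=cfg,
        matrix=matrix,
        annotations=annotations,
        probe_map=probe_map,
        truth=truth,
        qc_report=qc_report,
        sd_table=sd_table,
        mixture_target=mixture_target,
        mixture_comparison=mixture_comparison,
        filter_result=filter_result,
        dendrogram=dendrogram,
        assignment=assignment,
        enriched=enriched,
        marker_report=marker_report,
        correlates=correlates,
        manifest=manifest,
    )


def asdict_simconfig(sim: SimConfig) -> dict:
    d = asdict(sim)
    d["n_cells_per_type"] = list(sim.n_cells_per_type)
    return d


def build_manifest(
    cfg: PipelineConfig,
    matrix: ExpressionMatrix,
    filter_result: FilterResult,
    assignment: ClusterAssignment,
) -> dict:
    cfg_dict = {
        k: (asdict_simconfig(v) if isinstance(v, SimConfig) else v)
        for k, v in asdict(cfg).items()
    }
    cfg_dict["seed_genes"] = list(cfg.seed_genes)
    cfg_dict["qc_required"] = list(cfg.qc_required)
    cfg_dict["qc_excluded"] = list(cfg.qc_excluded)
    return {
        "package": {"name": "rgcmark", "version": __version__},
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": cfg_dict,
        "decisions": {
            "log2_transform": "log2(x+1) on linear-scale matrices",
            "sd_estimator": "sample SD (ddof=1)",
            "sd_filter_inequality": ">" if cfg.strict_sd_filter else ">=",
            "distance": "1 - Pearson r",
            "linkage": "average (UPGMA), lexicographic tie-break",
            "cluster_labels": "decreasing size, ties by smallest member id",
            "correlate_substrate": cfg.correlate_substrate,
            "gene_detection": "OR over mapped probes",
            "qc_policy": "report only; no cells dropped",
            "enriched_min_cluster_size": cfg.min_enriched_cluster_size,
        },
        "data": {
            "n_probes": matrix.shape[0],
            "n_cells": matrix.shape[1],
            "scale_tag": matrix.scale_tag,
        },
        "results": {
            "n_retained": filter_result.n_retained,
            "cluster_sizes": assignment.sizes(),
        },
        "seed": cfg.seed,
    }


def render_ordered_matrix(
    matrix: ExpressionMatrix,
    dendrogram: Dendrogram,
    gene_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Re-order matrix columns by dendrogram leaf order (heatmap export).

    Values are unchanged; optionally also re-orders rows by ``gene_order``.
    """
    order = dendrogram.leaf_order()
    if set(order) != set(matrix.cell_ids):
        raise ValueError("dendrogram leaves do not match matrix cells")
    out = matrix.values[order]
    if gene_order is not None:
        gene_order = list(gene_order)
        missing = [g for g in gene_order if g not in out.index]
        if missing:
            raise KeyError(f"unknown probe id(s) in gene_order: {missing[:5]}")
        out = out.loc[gene_order]
    return out
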