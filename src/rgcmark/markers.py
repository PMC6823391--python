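"""Marker-discovery queries over detection calls and correlation profiles.

These are the screens the study ran against its two single-cell datasets:
prevalence-based subset markers ("expressed in 7 or more of the 14 cells"),
seed-gene Pearson-correlate lists at a fixed cutoff (0.53 for the melanopsin
screen), cross-dataset correlate intersection, functional-class-restricted
genes, pairwise co-expression overlap, and gene-panel detection profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrixio import CellAnnotation, ExpressionMatrix, ProbeAnnotation
from .qc import detect_calls

DEFAULT_R_THRESHOLD = 0.53
DEFAULT_MIN_CELLS = 7


@dataclass
class CorrelateList:
    """Ranked seed-gene correlates: genes with r >= r_threshold, seed excluded."""

    seed_gene: str
    r_threshold: float
    entries: pd.DataFrame  # columns: gene, probe_id, r; sorted r desc, gene asc
    dataset: str = ""

    def genes(self) -> list[str]:
        return list(self.entries["gene"])

    def to_dict(self) -> dict:
        return {
            "seed_gene": self.seed_gene,
            "r_threshold": self.r_threshold,
            "dataset": self.dataset,
            "entries": self.entries.to_dict(orient="records"),
        }


def _resolve_probes(
    matrix: ExpressionMatrix, gene: str, probe_map: Optional[ProbeAnnotation]
) -> list[str]:
    if probe_map is not None:
        probes = [p for p in probe_map.probes_for(gene) if p in matrix.values.index]
    else:
        probes = [gene] if gene in matrix.values.index else []
    return probes


def prevalence_markers(
    matrix: ExpressionMatrix,
    cells: Sequence[str],
    detection_threshold: float,
    min_cells: int = DEFAULT_MIN_CELLS,
    probe_map: Optional[ProbeAnnotation] = None,
) -> pd.DataFrame:
    """Prevalence report over a cell subset.

    One row per gene detected in at least one cell: ``majority_subset`` when
    detected in >= ``min_cells`` cells, else ``restricted_subset``.  Ordered
    by prevalence descending, then gene ascending.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("cells must be nonempty")
    if min_cells > len(cells):
        raise ValueError(f"min_cells={min_cells} exceeds |cells|={len(cells)}")
    calls = detect_calls(matrix.subset(cells=cells), detection_threshold)
    n_det = calls.sum(axis=1)
    keep = n_det >= 1
    n_det = n_det[keep]
    genes = [
        (probe_map.symbol_for(p) or p) if probe_map else p for p in n_det.index
    ]
    out = pd.DataFrame(
        {
            "probe_id": n_det.index,
            "gene": genes,
            "n_cells_detected": n_det.to_numpy(dtype=int),
            "n_cells_total": len(cells),
        }
    )
    out["prevalence"] = out["n_cells_detected"] / out["n_cells_total"]
    out["category"] = np.where(
        out["n_cells_detected"] >= min_cells, "majority_subset", "restricted_subset"
    )
    return out.sort_values(
        ["prevalence", "gene", "probe_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def seed_correlates(
    matrix: ExpressionMatrix,
    seed_gene: str,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    cells: Optional[Sequence[str]] = None,
    probe_map: Optional[ProbeAnnotation] = None,
    dataset: str = "",
) -> CorrelateList:
    """Pearson correlates of every probe against a seed gene's profile.

    Correlation is computed on log2 signal across ``cells`` (all cells by
    default).  When the seed maps to several probes, the highest-variance one
    is the seed profile.  Zero-variance probes get r = 0, so any positive
    threshold excludes them.  Probes are collapsed to symbols keeping the
    best-scoring probe per gene; the seed gene itself is excluded.
    """
    sub = matrix if cells is None else matrix.subset(cells=list(cells))
    seed_probes = _resolve_probes(sub, seed_gene, probe_map)
    if not seed_probes:
        raise KeyError(f"seed gene {seed_gene!r} not mapped to any probe in the matrix")
    log2 = sub.log2()
    arr = log2.to_numpy()
    sds = arr.std(axis=1)
    seed_idx = [log2.index.get_loc(p) for p in seed_probes]
    seed_idx = max(seed_idx, key=lambda i: sds[i])
    if sds[seed_idx] == 0:
        raise ValueError(f"seed gene {seed_gene!r} has zero variance over these cells")
    seed_profile = arr[seed_idx]

    centered = arr - arr.mean(axis=1, keepdims=True)
    seed_c = seed_profile - seed_profile.mean()
    denom = np.sqrt((centered**2).sum(axis=1)) * np.sqrt((seed_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (centered @ seed_c) / denom
    r = np.where(denom > 0, r, 0.0)
    r = np.clip(np.nan_to_num(r, nan=0.0), -1.0, 1.0)

    genes = [
        (probe_map.symbol_for(p) or p) if probe_map else p for p in log2.index
    ]
    frame = pd.DataFrame({"gene": genes, "probe_id": log2.index, "r": r})
    seed_symbol = (
        probe_map.normalize_symbol(seed_gene) if probe_map else seed_gene
    )
    frame = frame[frame["gene"] != seed_symbol]
    frame = frame[~frame["probe_id"].isin(seed_probes)]
    # best-scoring probe per symbol
    frame = (
        frame.sort_values(["r", "probe_id"], ascending=[False, True])
        .drop_duplicates("gene", keep="first")
    )
    frame = frame[frame["r"] >= r_threshold]
    frame = frame.sort_values(["r", "gene"], ascending=[False, True]).reset_index(
        drop=True
    )
    return CorrelateList(
        seed_gene=seed_gene, r_threshold=float(r_threshold), entries=frame, dataset=dataset
    )


def cross_dataset_intersection(
    list_a: CorrelateList, list_b: CorrelateList
) -> pd.DataFrame:
    """Genes present in both correlate lists, with both r values.

    Sorted by min(r_a, r_b) descending.  Lists for different seed genes are
    allowed (the operation is generic) but produce a warning.
    """
    if list_a.seed_gene != list_b.seed_gene:
        warnings.warn(
            f"intersecting correlate lists for different seeds "
            f"({list_a.seed_gene!r} vs {list_b.seed_gene!r})",
            stacklevel=2,
        )
    a = list_a.entries[["gene", "r"]].rename(columns={"r": "r_a"})
    b = list_b.entries[["gene", "r"]].rename(columns={"r": "r_b"})
    merged = a.merge(b, on="gene", how="inner")
    merged["r_min"] = merged[["r_a", "r_b"]].min(axis=1)
    return (
        merged.sort_values(["r_min", "gene"], ascending=[False, True])
        .drop(columns="r_min")
        .reset_index(drop=True)
    )


def class_restricted_genes(
    matrix: ExpressionMatrix,
    annotations: Sequence[CellAnnotation],
    class_set: set[str],
    detection_threshold: float,
    min_in_prev: float = 0.75,
    max_out_prev: float = 0.25,
    probe_map: Optional[ProbeAnnotation] = None,
) -> pd.DataFrame:
    """Genes detected preferentially within a set of functional classes.

    Same prevalence-contrast contract as cluster-enriched ranking, with the
    in-group defined by functional-class labels.  Requires at least one
    annotated cell inside and outside the class set.
    """
    if not class_set:
        raise ValueError("class_set must be nonempty")
    by_cell = {a.cell_id: a.functional_class for a in annotations}
    labelled = [c for c in matrix.cell_ids if by_cell.get(c) is not None]
    in_cells = [c for c in labelled if by_cell[c] in class_set]
    out_cells = [c for c in labelled if by_cell[c] not in class_set]
    if not in_cells:
        raise ValueError(f"no cells with class in {sorted(class_set)}")
    if not out_cells:
        raise ValueError("no cells outside the class set to contrast against")
    calls = detect_calls(matrix, detection_threshold)
    in_prev = calls[in_cells].mean(axis=1)
    out_prev = calls[out_cells].mean(axis=1)
    score = in_prev - out_prev
    passes = (in_prev >= min_in_prev) & (out_prev <= max_out_prev)
    out = pd.DataFrame(
        {
            "probe_id": calls.index,
            "gene": [
                (probe_map.symbol_for(p) or p) if probe_map else p for p in calls.index
            ],
            "in_prevalence": in_prev.to_numpy(),
            "out_prevalence": out_prev.to_numpy(),
            "score": score.to_numpy(),
            "category": "class_restricted",
        }
    )[passes.to_numpy()]
    return out.sort_values(
        ["score", "gene", "probe_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def coexpression_overlap(
    matrix: ExpressionMatrix,
    gene_a: str,
    gene_b: str,
    cells: Sequence[str],
    detection_threshold: float,
    probe_map: Optional[ProbeAnnotation] = None,
) -> dict:
    """2x2 co-detection partition of ``cells`` for two genes.

    Returns counts (n_both, n_a_only, n_b_only, n_neither) and the cell ids
    in each category; the four counts always partition the cell set.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("cells must be nonempty")
    sub = matrix.subset(cells=cells)
    calls = detect_calls(sub, detection_threshold)
    out = {}
    det = {}
    for name, gene in (("a", gene_a), ("b", gene_b)):
        probes = _resolve_probes(sub, gene, probe_map)
        if not probes:
            raise KeyError(f"gene {gene!r} not mapped to any probe in the matrix")
        det[name] = calls.loc[probes].any(axis=0)
    both = det["a"] & det["b"]
    a_only = det["a"] & ~det["b"]
    b_only = det["b"] & ~det["a"]
    neither = ~det["a"] & ~det["b"]
    for key, mask in (
        ("both", both),
        ("a_only", a_only),
        ("b_only", b_only),
        ("neither", neither),
    ):
        out[f"n_{key}"] = int(mask.sum())
        out[f"cells_{key}"] = list(mask.index[mask])
    out["gene_a"], out["gene_b"] = gene_a, gene_b
    return out


def panel_query(
    matrix: ExpressionMatrix,
    gene_panel: Sequence[str],
    cells: Sequence[str],
    detection_threshold: float,
    probe_map: Optional[ProbeAnnotation] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Detection profile of a gene panel (e.g. ion-channel subunits).

    Returns (per-gene report in panel order, gene x cell boolean call grid,
    unmapped panel genes).  Unmapped genes are reported, not fatal, unless
    the whole panel is unmapped.
    """
    cells = list(cells)
    if not cells:
        raise ValueError("cells must be nonempty")
    sub = matrix.subset(cells=cells)
    calls = detect_calls(sub, detection_threshold)
    rows = []
    grid_rows = {}
    unmapped: list[str] = []
    for gene in gene_panel:
        probes = _resolve_probes(sub, gene, probe_map)
        if not probes:
            unmapped.append(gene)
            continue
        det = calls.loc[probes].any(axis=0)
        grid_rows[gene] = det
        rows.append(
            {
                "gene": gene,
                "n_cells_detected": int(det.sum()),
                "n_cells_total": len(cells),
                "prevalence": float(det.mean()),
                "category": "panel",
            }
        )
    if not rows:
        raise ValueError("no panel gene maps to any probe in the matrix")
    report = pd.DataFrame(rows)
    grid = pd.DataFrame(grid_rows).T
    grid = grid.loc[[g for g in gene_panel if g in grid.index]]
    return report, grid, unmapped
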