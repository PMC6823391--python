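"""Seeded synthetic expression matrices with planted marker/cluster structure.

The generator emulates the statistical geometry of a small single-cell
microarray study: a handful of target cells drawn from a few planted types, a
comparison group of non-target cells, and a probe population whose per-group
standard deviations form a two-component (noise / informative) mixture.

Probe roles
-----------
``noise``
    The dominant low-variance component: a flat baseline plus iid per-cell
    noise whose SD is drawn from the low mixture component.
``background_informative``
    High-variance probes.  In the target group their variance is split
    between between-type offsets (shared by all cells of a planted type) and
    per-cell noise; comparison cells get the full variance as per-cell noise
    (the comparison pool emulates a heterogeneous grab-bag of other cell
    classes).  Each probe additionally carries an independent group-level
    offset per group, which differentiates the two groups without inflating
    within-group SDs.
``marker_of_type_<t>``
    Detection-level ("on") in cells of planted type t, off elsewhere, plus a
    small additive noise drawn from the low component.
``pan_marker``
    On in every target cell, off in every comparison cell.  The first pan
    marker is given the symbol Sncg, the pan-RGC gene used by the library QC
    screen; two noise probes are named Rho and Glul so the contaminant side
    of the screen is exercised too.
``seed_module``
    A planted co-regulated module: the module seed plus ``n_module_genes``
    probes sharing one on/off pattern spanning the cells of ``module_type``
    and the first ``n_module_comparison_cells`` comparison cells (a program
    shared across the group boundary, as Pvalb itself is between RGCs and
    amacrine cells).  Because the pattern varies inside both groups, module
    probes survive the dual-group SD filter and are recoverable by the
    seed-correlate screen on the filtered substrate.

All log2 signals are clipped at 0 and emitted on linear scale as
``2**v - 1`` so the pipeline's log2(x+1) transform recovers the planted log2
values exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matrixio import CellAnnotation, ExpressionMatrix, ProbeAnnotation

_QC_REQUIRED_SYMBOL = "Sncg"
_QC_CONTAMINANT_SYMBOLS = ("Rho", "Glul")
MODULE_SEED_SYMBOL = "Modseed"


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Defaults mirror the study geometry: three planted target types of 9, 4
    and 1 cells against a 7-cell comparison group, 20,000 probes of which 82%
    belong to the low-SD noise component, with SD components
    N(0.8, 0.25) / N(4.0, 0.35) in log2-signal units.
    """

    n_probes: int = 20_000
    n_cells_per_type: Sequence[int] = (9, 4, 1, 7)
    n_types_target: int = 3
    frac_noise_probes: float = 0.82
    noise_sd_mean: float = 0.8
    noise_sd_sd: float = 0.25
    info_sd_mean: float = 4.0
    info_sd_sd: float = 0.35
    n_markers_per_type: int = 25
    n_pan_markers: int = 25
    detection_high: float = 10.0
    detection_low: float = 3.0
    seed: int = 0
    # Additional structure knobs (defaults chosen once; see docs/methods.md).
    noise_baseline: float = 3.0
    info_baseline: float = 10.0
    type_structure_frac: float = 0.25  # informative target-group variance from type offsets
    group_effect_frac: float = 0.4   # group-offset variance as a multiple of the probe SD^2
    comparison_group_effect_frac: float = 1.0  # comparison group's shared-offset variance
    n_module_genes: int = 10
    n_module_comparison_cells: int = 3
    module_type: int = 1
    include_qc_genes: bool = True
    noise_sd_clip: tuple[float, float] = (0.05, math.inf)
    info_sd_clip: tuple[float, float] = (0.5, math.inf)
    type_class_labels: Optional[Sequence[Optional[str]]] = None
    dataset_name: str = "synthetic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_noise_probes <= 1.0):
            raise ValueError("frac_noise_probes must lie in [0, 1]")
        if self.noise_sd_mean >= self.info_sd_mean:
            raise ValueError("noise_sd_mean must be below info_sd_mean (bimodal SDs)")
        counts = (
            self.n_probes,
            self.n_markers_per_type,
            self.n_pan_markers,
            self.n_module_genes,
            self.n_module_comparison_cells,
            *self.n_cells_per_type,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if not (0 <= self.n_types_target <= len(self.n_cells_per_type)):
            raise ValueError("n_types_target out of range")
        if any(sd < 0 for sd in (self.noise_sd_sd, self.info_sd_sd)):
            raise ValueError("SD spreads must be >= 0")
        if self.detection_high <= self.detection_low:
            raise ValueError("detection_high must exceed detection_low")
        if not (0.0 <= self.type_structure_frac < 1.0):
            raise ValueError("type_structure_frac must lie in [0, 1)")
        if self.n_module_genes and not (1 <= self.module_type <= self.n_types_target):
            raise ValueError("module_type must name a target type")
        n_comp_cells = sum(self.n_cells_per_type[self.n_types_target:])
        if self.n_module_genes and self.n_module_comparison_cells > n_comp_cells:
            raise ValueError("n_module_comparison_cells exceeds comparison group size")

    @property
    def n_cells(self) -> int:
        return int(sum(self.n_cells_per_type))

    def structured_probe_count(self) -> int:
        n = self.n_pan_markers + self.n_markers_per_type * len(self.n_cells_per_type)
        if self.n_module_genes:
            n += self.n_module_genes + 1  # + module seed
        return n


@dataclass
class SimTruth:
    """Planted ground truth: cell types, probe roles, and planted SD draws."""

    cell_types: dict[str, int]
    probe_roles: dict[str, str]
    planted_sd: pd.Series  # per-probe SD-component draw (log2 units)
    module_seed_probe: Optional[str]
    module_on_cells: list[str]
    config: SimConfig

    def probes_with_role(self, role: str) -> list[str]:
        return [p for p, r in self.probe_roles.items() if r == role]

    def marker_probes(self, type_index: int) -> list[str]:
        return self.probes_with_role(f"marker_of_type_{type_index}")

    def module_probes(self) -> list[str]:
        return self.probes_with_role("seed_module")

    def planted_sd_table(self) -> pd.DataFrame:
        """Per-probe planted SDs as a (sd_target, sd_comparison) table.

        For noise and background-informative probes the planted per-group SD
        is the component draw itself; for on/off structured probes it is the
        additive-noise draw (the deterministic on/off pattern contributes
        extra empirical variance on top and is not included here).
        """
        return pd.DataFrame(
            {"sd_target": self.planted_sd, "sd_comparison": self.planted_sd}
        )

    def partition_labels(self, cells: Sequence[str]) -> list[int]:
        return [self.cell_types[c] for c in cells]


def _clip(draws: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    lo, hi = bounds
    return np.clip(draws, lo, None if math.isinf(hi) else hi)


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, list[CellAnnotation], SimTruth, ProbeAnnotation]:
    """Generate a seeded synthetic dataset.

    Returns the linear-scale expression matrix, the per-cell annotations, the
    planted truth, and a probe->symbol map.  Identical configs (including
    seed) give bit-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # ---- cells ---------------------------------------------------------------
    cell_ids: list[str] = []
    cell_types: dict[str, int] = {}
    groups: list[str] = []
    classes: list[Optional[str]] = []
    for t, size in enumerate(cfg.n_cells_per_type, start=1):
        is_target = t <= cfg.n_types_target
        prefix = "T" if is_target else "C"
        label = None
        if cfg.type_class_labels is not None and t - 1 < len(cfg.type_class_labels):
            label = cfg.type_class_labels[t - 1]
        for i in range(1, size + 1):
            cid = f"{prefix}{t}_{i:02d}"
            cell_ids.append(cid)
            cell_types[cid] = t
            groups.append("target" if is_target else "comparison")
            classes.append(label)
    n_cells = len(cell_ids)
    type_arr = np.array([cell_types[c] for c in cell_ids])
    target_mask = np.array([g == "target" for g in groups])
    comparison_cells = [c for c, g in zip(cell_ids, groups) if g == "comparison"]

    # ---- probe bookkeeping ---------------------------------------------------
    n_structured = cfg.structured_probe_count()
    n_noise = int(round(cfg.frac_noise_probes * cfg.n_probes))
    n_background = cfg.n_probes - n_noise - n_structured
    if n_background < 0:
        raise ValueError(
            "config leaves no room for structured probes: lower frac_noise_probes "
            "or the marker/pan/module counts"
        )

    probe_ids = [f"P{i:05d}" for i in range(1, cfg.n_probes + 1)]
    roles: list[str] = []
    symbols: dict[str, str] = {}
    module_on_cells: list[str] = []
    module_seed_probe: Optional[str] = None

    # structured block first, then background, then noise
    for j in range(cfg.n_pan_markers):
        roles.append("pan_marker")
    for t in range(1, len(cfg.n_cells_per_type) + 1):
        for _ in range(cfg.n_markers_per_type):
            roles.append(f"marker_of_type_{t}")
    if cfg.n_module_genes:
        roles.append("seed_module")  # the seed itself
        roles.extend(["seed_module"] * cfg.n_module_genes)
    roles.extend(["background_informative"] * n_background)
    roles.extend(["noise"] * n_noise)
    assert len(roles) == cfg.n_probes

    # symbols: special names for QC genes and the module; generic G-symbols else
    for pid in probe_ids:
        symbols[pid] = f"G{pid[1:]}"
    if cfg.include_qc_genes and cfg.n_pan_markers:
        symbols[probe_ids[0]] = _QC_REQUIRED_SYMBOL
    if cfg.n_module_genes:
        start = cfg.n_pan_markers + cfg.n_markers_per_type * len(cfg.n_cells_per_type)
        module_seed_probe = probe_ids[start]
        symbols[module_seed_probe] = MODULE_SEED_SYMBOL
        for m in range(1, cfg.n_module_genes + 1):
            symbols[probe_ids[start + m]] = f"Mod{m:02d}"
    if cfg.include_qc_genes and n_noise >= len(_QC_CONTAMINANT_SYMBOLS):
        first_noise = cfg.n_probes - n_noise
        for k, sym in enumerate(_QC_CONTAMINANT_SYMBOLS):
            symbols[probe_ids[first_noise + k]] = sym

    # ---- planted SDs ---------------------------------------------------------
    role_arr = np.array(roles)
    is_noise = role_arr == "noise"
    is_background = role_arr == "background_informative"
    is_structured = ~is_noise & ~is_background

    sd = np.empty(cfg.n_probes)
    sd[is_structured] = _clip(
        rng.normal(cfg.noise_sd_mean, cfg.noise_sd_sd, int(is_structured.sum())),
        (cfg.noise_sd_clip[0], 0.25 * (cfg.detection_high - cfg.detection_low)),
    )
    sd[is_background] = _clip(
        rng.normal(cfg.info_sd_mean, cfg.info_sd_sd, int(is_background.sum())),
        cfg.info_sd_clip,
    )
    sd[is_noise] = _clip(
        rng.normal(cfg.noise_sd_mean, cfg.noise_sd_sd, int(is_noise.sum())),
        cfg.noise_sd_clip,
    )

    # ---- log2 signal ---------------------------------------------------------
    V = np.empty((cfg.n_probes, n_cells))

    # noise probes: flat baseline + iid noise
    idx = np.where(is_noise)[0]
    V[idx] = cfg.noise_baseline + sd[idx, None] * rng.standard_normal((len(idx), n_cells))

    # background informative probes: group offsets + type offsets + per-cell noise
    idx = np.where(is_background)[0]
    nb = len(idx)
    target_sizes = [s for t, s in enumerate(cfg.n_cells_per_type, start=1) if t <= cfg.n_types_target]
    n_t = sum(target_sizes)
    # kappa = expected fraction of type-offset variance visible in the target
    # sample variance for this type-size layout
    if cfg.n_types_target >= 2 and n_t >= 2:
        kappa = 1.0 - sum(s * (s - 1) for s in target_sizes) / (n_t * (n_t - 1))
    else:
        kappa = 0.0
    rho = cfg.type_structure_frac if kappa > 0 else 0.0
    b_type = math.sqrt(rho / kappa) if rho > 0 else 0.0
    w_target = math.sqrt(1.0 - rho)
    g = math.sqrt(cfg.group_effect_frac)
    g_comp = math.sqrt(cfg.comparison_group_effect_frac)
    if nb:
        u = rng.normal(0.0, 1.0, (nb, 2))  # per-group offsets (unit scale)
        u[:, 0] *= g * sd[idx]
        u[:, 1] *= g_comp * sd[idx]
        delta = rng.normal(0.0, 1.0, (nb, cfg.n_types_target)) * (b_type * sd[idx, None])
        eps = rng.standard_normal((nb, n_cells))
        vals = np.empty((nb, n_cells))
        for c in range(n_cells):
            t = type_arr[c]
            if target_mask[c]:
                vals[:, c] = (
                    cfg.info_baseline
                    + u[:, 0]
                    + (delta[:, t - 1] if b_type > 0 else 0.0)
                    + w_target * sd[idx] * eps[:, c]
                )
            else:
                vals[:, c] = cfg.info_baseline + u[:, 1] + sd[idx] * eps[:, c]
        V[idx] = vals

    # on/off structured probes
    if cfg.n_module_genes:
        mod_type_cells = [c for c in cell_ids if cell_types[c] == cfg.module_type]
        module_on_cells = mod_type_cells + comparison_cells[: cfg.n_module_comparison_cells]
    on_sets: dict[str, np.ndarray] = {"pan_marker": target_mask}
    for t in range(1, len(cfg.n_cells_per_type) + 1):
        on_sets[f"marker_of_type_{t}"] = type_arr == t
    if cfg.n_module_genes:
        on_sets["seed_module"] = np.array([c in module_on_cells for c in cell_ids])
    idx = np.where(is_structured)[0]
    if len(idx):
        eps = rng.standard_normal((len(idx), n_cells))
        for row, p in enumerate(idx):
            on = on_sets[roles[p]]
            level = np.where(on, cfg.detection_high, cfg.detection_low)
            V[p] = level + sd[p] * eps[row]

    np.clip(V, 0.0, None, out=V)
    linear = np.exp2(V) - 1.0

    matrix = ExpressionMatrix(
        pd.DataFrame(linear, index=probe_ids, columns=cell_ids), "mas5_linear"
    )
    annotations = [
        CellAnnotation(cid, cfg.dataset_name, grp, fclass)
        for cid, grp, fclass in zip(cell_ids, groups, classes)
    ]
    truth = SimTruth(
        cell_types=cell_types,
        probe_roles=dict(zip(probe_ids, roles)),
        planted_sd=pd.Series(sd, index=probe_ids, name="planted_sd"),
        module_seed_probe=module_seed_probe,
        module_on_cells=module_on_cells,
        config=cfg,
    )
    return matrix, annotations, truth, ProbeAnnotation(symbols)


def sd_bimodality_check(
    matrix: ExpressionMatrix,
    groups: dict[str, str],
    config: SimConfig,
    n_bins: int = 60,
) -> dict:
    """Diagnostic for the planted bimodal SD structure.

    Computes per-group SD histograms (log2 scale) and the fraction of probes
    whose SD exceeds the midpoint between the two planted component means in
    either group.  For a default config that fraction approximates
    ``1 - frac_noise_probes``.
    """
    from .variance import per_group_sd

    table = per_group_sd(matrix, groups)
    midpoint = 0.5 * (config.noise_sd_mean + config.info_sd_mean)
    above = (table["sd_target"] > midpoint) | (table["sd_comparison"] > midpoint)
    hists = {}
    for col in ("sd_target", "sd_comparison"):
        counts, edges = np.histogram(table[col].to_numpy(), bins=n_bins)
        hists[col] = {"counts": counts.tolist(), "edges": edges.tolist()}
    return {
        "midpoint": midpoint,
        "fraction_above_midpoint": float(above.mean()),
        "fraction_above_target": float((table["sd_target"] > midpoint).mean()),
        "fraction_above_comparison": float((table["sd_comparison"] > midpoint).mean()),
        "expected_fraction": 1.0 - config.frac_noise_probes,
        "n_probes": int(len(table)),
        "histograms": hists,
    }
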