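"""In-silico library QC: required-marker presence, contaminant-marker absence.

The bench assay this emulates screened each single-cell cDNA library for a
pan-RGC gene (Sncg) and against contaminant markers (rod Rhodopsin, Mueller
glia Glutamine synthetase).  Here the same rule is applied as a detection
gate on the expression matrix: a gene counts as detected in a cell when any
of its probes reaches the log2-signal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .matrixio import ExpressionMatrix, ProbeAnnotation

DEFAULT_DETECTION_THRESHOLD = 6.0  # log2 scale; MAS5 linear signal >= 63


@dataclass(frozen=True)
class QCRule:
    required_genes: tuple[str, ...] = ("Sncg",)
    excluded_genes: tuple[str, ...] = ("Rho", "Glul")
    detection_threshold: float = DEFAULT_DETECTION_THRESHOLD

    def __post_init__(self) -> None:
        overlap = set(self.required_genes) & set(self.excluded_genes)
        if overlap:
            raise ValueError(f"genes both required and excluded: {sorted(overlap)}")
        if not np.isfinite(self.detection_threshold):
            raise ValueError("detection threshold must be finite")


def detect_calls(matrix: ExpressionMatrix, detection_threshold: float) -> pd.DataFrame:
    """Binary expressed/absent calls: log2 signal >= threshold.

    Linear-scale matrices are transformed with log2(x + 1) first, so a linear
    MAS5 value of 63 at a threshold of 6 is called detected (log2 64 = 6).
    """
    return matrix.log2() >= detection_threshold


def gene_detected(
    calls: pd.DataFrame, probe_map: ProbeAnnotation, gene: str
) -> pd.Series:
    """Per-cell detection of a gene: OR over its mapped probes."""
    probes = [p for p in probe_map.probes_for(gene) if p in calls.index]
    if not probes:
        raise KeyError(f"gene {gene!r} has no mapped probe in the matrix")
    return calls.loc[probes].any(axis=0)


def library_qc(
    matrix: ExpressionMatrix,
    probe_map: ProbeAnnotation,
    rule: QCRule = QCRule(),
) -> pd.DataFrame:
    """Apply a QC rule per cell.

    A cell passes iff every required gene is detected and no excluded gene
    is.  Returns a frame indexed by cell id with columns ``qc_pass`` and
    ``reasons`` (semicolon-joined violated clauses; empty when passing).
    A rule gene without any mapped probe is a hard error.
    """
    calls = detect_calls(matrix, rule.detection_threshold)
    required = {g: gene_detected(calls, probe_map, g) for g in rule.required_genes}
    excluded = {g: gene_detected(calls, probe_map, g) for g in rule.excluded_genes}
    records = []
    for cell in matrix.cell_ids:
        reasons = [
            f"required gene {g} not detected" for g, det in required.items() if not det[cell]
        ] + [
            f"excluded gene {g} detected" for g, det in excluded.items() if det[cell]
        ]
        records.append((cell, not reasons, ";".join(reasons)))
    return pd.DataFrame(
        records, columns=["cell_id", "qc_pass", "reasons"]
    ).set_index("cell_id")


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t")
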