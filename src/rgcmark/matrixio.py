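"""Readers, writers and validated containers for expression data.

The on-disk matrix dialect is the tab-delimited layout used by GEO
series-matrix deposits: first row is the cell-id header, first column the
probeset (or gene-symbol) ids, and any line starting with ``!`` is metadata
and is skipped on read.  One metadata line, ``!scale_tag``, is written and
honoured on read so a matrix remembers the scale it was saved on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SCALE_TAGS = ("mas5_linear", "tpm", "log2_already")

#: Functional classes recorded by the physiological characterisation.
FUNCTIONAL_CLASSES = frozenset(
    {
        "ON_alpha",
        "OFF_transient_alpha",
        "OFF_sustained_alpha",
        "ON_DS",
        "ONOFF_DS",
        "ON_OS",
        "ON_transient_RF",
        "OFF_transient_RF",
        "PixON",
        "J_RGC",
        "LED",
        "SbC",
        "size_selector",
        "other",
        "unknown",
    }
)

#: Historic/variant gene spellings normalised to current MGI symbols.
GENE_ALIASES = {"Mfab": "Mafb"}


def _find_duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for it in items:
        if it in seen and it not in dups:
            dups.append(it)
        seen.add(it)
    return dups


@dataclass
class ExpressionMatrix:
    """A probe-by-cell grid of normalized expression signal.

    ``values`` is a pandas DataFrame indexed by probe id with one column per
    cell.  ``scale_tag`` records the scale the numbers live on:
    ``mas5_linear`` and ``tpm`` are linear, non-negative scales; a matrix
    tagged ``log2_already`` bypasses the pipeline's log2(x+1) transform.
    """

    values: pd.DataFrame
    scale_tag: str = "mas5_linear"

    def __post_init__(self) -> None:
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(
                f"unknown scale_tag {self.scale_tag!r}; expected one of {SCALE_TAGS}"
            )
        self.values = self.values.astype(float)
        dups = _find_duplicates(list(self.values.index))
        if dups:
            raise ValueError(f"duplicate probe id(s): {', '.join(dups)}")
        dups = _find_duplicates(list(self.values.columns))
        if dups:
            raise ValueError(f"duplicate cell id(s): {', '.join(dups)}")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("expression matrix contains non-finite values")
        if self.scale_tag in ("mas5_linear", "tpm") and arr.size and (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value {arr[i, j]} at probe {self.values.index[i]!r}, "
                f"cell {self.values.columns[j]!r} under scale {self.scale_tag}"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def log2(self) -> pd.DataFrame:
        """Return log2-scale values: log2(x + 1) for linear tags, as-is otherwise."""
        if self.scale_tag == "log2_already":
            return self.values.copy()
        return np.log2(self.values + 1.0)

    def subset(
        self,
        probes: Optional[Iterable[str]] = None,
        cells: Optional[Iterable[str]] = None,
    ) -> "ExpressionMatrix":
        vals = self.values
        if probes is not None:
            probes = list(probes)
            missing = [p for p in probes if p not in vals.index]
            if missing:
                raise KeyError(f"unknown probe id(s): {', '.join(missing[:5])}")
            vals = vals.loc[probes]
        if cells is not None:
            cells = list(cells)
            missing = [c for c in cells if c not in vals.columns]
            if missing:
                raise KeyError(f"unknown cell id(s): {', '.join(missing[:5])}")
            vals = vals[cells]
        return ExpressionMatrix(vals.copy(), self.scale_tag)


@dataclass(frozen=True)
class CellAnnotation:
    """Per-cell metadata: provenance, contrast group, and functional class."""

    cell_id: str
    dataset: str
    group: str  # "target" or "comparison"
    functional_class: Optional[str] = None
    qc_pass: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.group not in ("target", "comparison"):
            raise ValueError(
                f"group for cell {self.cell_id!r} must be 'target' or 'comparison', "
                f"got {self.group!r}"
            )
        if self.functional_class is not None and self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"functional_class {self.functional_class!r} not in vocabulary"
            )


class ProbeAnnotation:
    """A probe-id -> gene-symbol map (many probes may share a symbol).

    Symbols are normalised through a small alias table so historic spellings
    resolve to the same gene.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._probe_to_symbol: dict[str, str] = {}
        self._symbol_to_probes: dict[str, list[str]] = {}
        for probe, symbol in mapping.items():
            symbol = self.normalize_symbol(symbol)
            if probe in self._probe_to_symbol and self._probe_to_symbol[probe] != symbol:
                raise ValueError(f"probe {probe!r} mapped to more than one symbol")
            self._probe_to_symbol[probe] = symbol
            self._symbol_to_probes.setdefault(symbol, []).append(probe)

    @staticmethod
    def normalize_symbol(symbol: str) -> str:
        return GENE_ALIASES.get(symbol, symbol)

    def symbol_for(self, probe: str) -> Optional[str]:
        return self._probe_to_symbol.get(probe)

    def probes_for(self, symbol: str) -> list[str]:
        return list(self._symbol_to_probes.get(self.normalize_symbol(symbol), []))

    def __len__(self) -> int:
        return len(self._probe_to_symbol)

    def __contains__(self, probe: str) -> bool:
        return probe in self._probe_to_symbol

    def items(self):
        return self._probe_to_symbol.items()

    @classmethod
    def identity(cls, probe_ids: Iterable[str]) -> "ProbeAnnotation":
        """Map every probe to itself (gene-level matrices)."""
        return cls({p: p for p in probe_ids})


# -- matrix I/O ---------------------------------------------------------------

def read_matrix(path, scale_tag: Optional[str] = None) -> ExpressionMatrix:
    """Read a tab-delimited probe-by-cell matrix.

    Lines starting with ``!`` are series-matrix metadata and are skipped,
    except for ``!scale_tag<TAB><tag>`` which supplies the scale when the
    ``scale_tag`` argument is None.  Defaults to ``mas5_linear`` when neither
    is present.
    """
    path = Path(path)
    file_tag: Optional[str] = None
    header: Optional[list[str]] = None
    probe_ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("!"):
                parts = line[1:].split("\t")
                if parts and parts[0] == "scale_tag" and len(parts) > 1:
                    file_tag = parts[1].strip()
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields[1:]]
                continue
            probe_ids.append(fields[0])
            vals = []
            for j, tok in enumerate(fields[1:], start=1):
                try:
                    vals.append(float(tok))
                except ValueError:
                    raise ValueError(
                        f"non-numeric value {tok!r} at line {lineno}, column {j + 1} "
                        f"(probe {fields[0]!r})"
                    ) from None
            if header and len(vals) != len(header):
                raise ValueError(
                    f"row for probe {fields[0]!r} has {len(vals)} values, "
                    f"expected {len(header)}"
                )
            rows.append(vals)
    if header is None:
        raise ValueError(f"{path}: no header line found")
    dups = _find_duplicates(probe_ids)
    if dups:
        raise ValueError(f"duplicate probe id(s): {', '.join(dups)}")
    dups = _find_duplicates(header)
    if dups:
        raise ValueError(f"duplicate cell id(s): {', '.join(dups)}")
    tag = scale_tag or file_tag or "mas5_linear"
    values = pd.DataFrame(
        np.asarray(rows, dtype=float).reshape(len(probe_ids), len(header)),
        index=probe_ids,
        columns=header,
    )
    return ExpressionMatrix(values, tag)


def write_matrix(matrix: ExpressionMatrix, path) -> Path:
    """Write a matrix in the tab-delimited dialect; round-trips bit-exactly."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"!scale_tag\t{matrix.scale_tag}\n")
        fh.write("probe_id\t" + "\t".join(matrix.cell_ids) + "\n")
        arr = matrix.values.to_numpy()
        for i, probe in enumerate(matrix.probe_ids):
            fh.write(probe + "\t" + "\t".join(repr(float(v)) for v in arr[i]) + "\n")
    return path


# -- annotation I/O -----------------------------------------------------------

def _split_delimited(line: str, delim: str) -> list[str]:
    return [f.strip() for f in line.rstrip("\n").split(delim)]


def read_annotations(path) -> list[CellAnnotation]:
    """Read a CSV/TSV cell-annotation table.

    Required columns: ``cell_id``, ``dataset``, ``group``; optional:
    ``functional_class``, ``qc_pass``.  Unknown functional-class tokens map to
    ``"other"`` with a warning; a cell annotated twice within one dataset is a
    hard error.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [l for l in fh if l.strip()]
    if not lines:
        raise ValueError(f"{path}: empty annotation file")
    delim = "\t" if "\t" in lines[0] else ","
    header = _split_delimited(lines[0], delim)
    required = {"cell_id", "dataset", "group"}
    if not required.issubset(header):
        raise ValueError(f"{path}: annotation header must contain {sorted(required)}")
    idx = {name: header.index(name) for name in header}
    out: list[CellAnnotation] = []
    seen: set[tuple[str, str]] = set()
    for line in lines[1:]:
        fields = _split_delimited(line, delim)
        cell = fields[idx["cell_id"]]
        dataset = fields[idx["dataset"]]
        key = (dataset, cell)
        if key in seen:
            raise ValueError(f"cell {cell!r} annotated twice in dataset {dataset!r}")
        seen.add(key)
        fclass: Optional[str] = None
        if "functional_class" in idx and len(fields) > idx["functional_class"]:
            tok = fields[idx["functional_class"]]
            if tok:
                if tok not in FUNCTIONAL_CLASSES:
                    warnings.warn(
                        f"unknown functional_class {tok!r} for cell {cell!r}; "
                        "recorded as 'other'",
                        stacklevel=2,
                    )
                    tok = "other"
                fclass = tok
        qc: Optional[bool] = None
        if "qc_pass" in idx and len(fields) > idx["qc_pass"] and fields[idx["qc_pass"]]:
            qc = fields[idx["qc_pass"]].lower() in ("1", "true", "yes", "pass")
        out.append(CellAnnotation(cell, dataset, fields[idx["group"]], fclass, qc))
    return out


def write_annotations(annotations: Sequence[CellAnnotation], path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("cell_id\tdataset\tgroup\tfunctional_class\tqc_pass\n")
        for a in annotations:
            fh.write(
                f"{a.cell_id}\t{a.dataset}\t{a.group}\t"
                f"{a.functional_class or ''}\t"
                f"{'' if a.qc_pass is None else str(a.qc_pass)}\n"
            )
    return path


def annotations_to_frame(annotations: Sequence[CellAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [a.cell_id for a in annotations],
            "dataset": [a.dataset for a in annotations],
            "group": [a.group for a in annotations],
            "functional_class": [a.functional_class for a in annotations],
            "qc_pass": [a.qc_pass for a in annotations],
        }
    ).set_index("cell_id")


def group_map(annotations: Sequence[CellAnnotation]) -> dict[str, str]:
    """cell_id -> group ('target'/'comparison') mapping."""
    return {a.cell_id: a.group for a in annotations}


def read_probe_map(path) -> ProbeAnnotation:
    """Read a two-column (probe_id, gene_symbol) TSV into a ProbeAnnotation."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "!")):
                continue
            fields = line.split("\t")
            if fields[0] == "probe_id":
                continue
            if len(fields) < 2 or not fields[1].strip():
                continue  # unmapped probe
            if fields[0] in mapping and mapping[fields[0]] != fields[1].strip():
                raise ValueError(f"probe {fields[0]!r} mapped to more than one symbol")
            mapping[fields[0]] = fields[1].strip()
    return ProbeAnnotation(mapping)


def write_probe_map(probe_map: ProbeAnnotation, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("probe_id\tgene_symbol\n")
        for probe, symbol in probe_map.items():
            fh.write(f"{probe}\t{symbol}\n")
    return path
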