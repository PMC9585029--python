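"""Readers/writers for the package's TSV formats, config loading and dataset validation.

All on-disk identifiers are strings; in memory each node type gets contiguous
integer indices whose order is recorded in the containers' label lists, so a
matrix written and re-read always comes back with the same row/column order.
TSV (not CSV) is used throughout because gene symbols containing commas exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class DataFormatError(ValueError):
    """Raised when an input file violates the expected TSV layout."""


@dataclass
class AssociationMatrix:
    """Binary association matrix with ordered string labels on both axes."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray  # shape (len(row_ids), len(col_ids)), entries in {0,1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match label counts "
                f"({len(self.row_ids)}, {len(self.col_ids)})"
            )
        bad = set(np.unique(self.values)) - {0, 1}
        if bad:
            raise ValueError(f"association matrix entries must be 0/1, found {sorted(bad)}")
        self.values = self.values.astype(np.int8)
        self._row_index = {r: i for i, r in enumerate(self.row_ids)}
        self._col_index = {c: j for j, c in enumerate(self.col_ids)}

    @property
    def n_positives(self) -> int:
        return int(self.values.sum())

    def row_index(self, row_id: str) -> int:
        return self._row_index[row_id]

    def col_index(self, col_id: str) -> int:
        return self._col_index[col_id]

    def ones(self) -> list[tuple[str, str]]:
        """All (row_id, col_id) pairs with a 1 entry, in row-major order."""
        rr, cc = np.nonzero(self.values)
        return [(self.row_ids[i], self.col_ids[j]) for i, j in zip(rr, cc)]

    def row_partners(self, row_id: str) -> list[str]:
        """Column labels associated with one row (e.g. the diseases of a lncRNA)."""
        mask = self.values[self._row_index[row_id]] == 1
        return [c for c, m in zip(self.col_ids, mask) if m]


@dataclass
class LabeledMatrix:
    """Square real-valued matrix (similarity) with one ordered label list."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"expected square {n}x{n} matrix, got {self.values.shape}")
        self._index = {d: i for i, d in enumerate(self.ids)}

    def index(self, node_id: str) -> int:
        return self._index[node_id]

    def submatrix(self, ids_a: list[str], ids_b: list[str]) -> np.ndarray:
        ia = [self._index[a] for a in ids_a]
        ib = [self._index[b] for b in ids_b]
        return self.values[np.ix_(ia, ib)]


@dataclass
class Dataset:
    """A loaded study dataset: LD and LM associations plus DSS and/or LFS."""

    ld: AssociationMatrix
    lm: AssociationMatrix
    dss: LabeledMatrix | None = None
    lfs: LabeledMatrix | None = None


def read_edge_list(path: str | Path, binary: bool = True) -> AssociationMatrix:
    """Read a two-column (plus optional weight) TSV edge list into a binary matrix.

    Labels are sorted and de-duplicated; duplicate edges collapse to a single 1
    with a warning. Malformed lines are rejected with their line number.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3) or not parts[0] or not parts[1]:
                raise DataFormatError(f"{path}:{lineno}: expected 2 or 3 tab-separated fields, got {line!r}")
            edges.append((parts[0], parts[1]))
    if not edges:
        raise DataFormatError(f"{path}: empty edge list")
    if len(set(edges)) < len(edges):
        warnings.warn(f"{path}: {len(edges) - len(set(edges))} duplicate edge(s) collapsed")
    rows = sorted({u for u, _ in edges})
    cols = sorted({v for _, v in edges})
    ri = {r: i for i, r in enumerate(rows)}
    ci = {c: j for j, c in enumerate(cols)}
    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for u, v in edges:
        values[ri[u], ci[v]] = 1
    return AssociationMatrix(rows, cols, values)


def write_edge_list(am: AssociationMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in am.ones():
            fh.write(f"{u}\t{v}\n")


def edges_to_matrix(
    edges: list[tuple[str, str]], row_ids: list[str], col_ids: list[str]
) -> AssociationMatrix:
    """Build an AssociationMatrix on fixed label lists from an edge list."""
    ri = {r: i for i, r in enumerate(row_ids)}
    ci = {c: j for j, c in enumerate(col_ids)}
    values = np.zeros((len(row_ids), len(col_ids)), dtype=np.int8)
    for u, v in edges:
        if u not in ri or v not in ci:
            raise DataFormatError(f"edge ({u}, {v}) references an unknown label")
        values[ri[u], ci[v]] = 1
    return AssociationMatrix(list(row_ids), list(col_ids), values)


def align_lncrna_labels(
    ld: AssociationMatrix, lm: AssociationMatrix
) -> tuple[AssociationMatrix, AssociationMatrix]:
    """Re-index LD and LM onto the sorted union of their lncRNA labels.

    Edge lists only mention lncRNAs that have at least one edge in that file,
    so the two matrices routinely disagree on their row sets; downstream
    stages require one shared, ordered lncRNA registry.
    """
    rows = sorted(set(ld.row_ids) | set(lm.row_ids))

    def reindex(am: AssociationMatrix) -> AssociationMatrix:
        values = np.zeros((len(rows), len(am.col_ids)), dtype=np.int8)
        for i, r in enumerate(rows):
            if r in am._row_index:
                values[i] = am.values[am.row_index(r)]
        return AssociationMatrix(rows, list(am.col_ids), values)

    return reindex(ld), reindex(lm)


def read_labeled_matrix(path: str | Path) -> AssociationMatrix | LabeledMatrix:
    """Read a labeled matrix TSV (first row = column ids, first column = row ids).

    Returns a LabeledMatrix when the matrix is square with identical row/column
    labels (a similarity matrix), otherwise an AssociationMatrix.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows == cols:
        return LabeledMatrix(rows, df.to_numpy(dtype=float))
    return AssociationMatrix(rows, cols, df.to_numpy())


def write_labeled_matrix(mat: AssociationMatrix | LabeledMatrix, path: str | Path) -> None:
    if isinstance(mat, LabeledMatrix):
        df = pd.DataFrame(mat.values, index=mat.ids, columns=mat.ids)
        df.to_csv(path, sep="\t", float_format="%.12g")
    else:
        df = pd.DataFrame(mat.values, index=mat.row_ids, columns=mat.col_ids)
        df.to_csv(path, sep="\t")


def read_dag_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Read a child<TAB>parent disease-DAG edge list."""
    path = Path(path)
    out: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise DataFormatError(f"{path}:{lineno}: expected child<TAB>parent, got {line!r}")
            out.append((parts[0], parts[1]))
    if not out:
        raise DataFormatError(f"{path}: empty DAG edge list")
    return out


def load_config(path: str | Path) -> dict:
    """Load the shared YAML config; returns {} for an empty file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


@dataclass
class ValidationReport:
    checks: dict[str, tuple[bool, str]] = field(default_factory=dict)

    def record(self, name: str, passed: bool, detail: str = "") -> None:
        self.checks[name] = (passed, detail)

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    def failures(self) -> dict[str, str]:
        return {k: d for k, (ok, d) in self.checks.items() if not ok}


def validate_dataset(ds: Dataset) -> ValidationReport:
    """Machine-readable consistency checks on a loaded dataset."""
    rep = ValidationReport()

    same_lnc = ds.ld.row_ids == ds.lm.row_ids
    detail = "" if same_lnc else (
        f"LD/LM lncRNA label mismatch, e.g. {sorted(set(ds.ld.row_ids) ^ set(ds.lm.row_ids))[:3]}"
    )
    rep.record("lncRNA_labels_consistent", same_lnc, detail)

    for name, am in (("LD", ds.ld), ("LM", ds.lm)):
        binary = bool(np.isin(am.values, (0, 1)).all())
        rep.record(f"{name}_binary", binary, "" if binary else "non 0/1 entries found")

    for name, sm in (("DSS", ds.dss), ("LFS", ds.lfs)):
        if sm is None:
            continue
        sym = bool(np.allclose(sm.values, sm.values.T, atol=1e-12))
        rep.record(f"{name}_symmetric", sym, "" if sym else "matrix is not symmetric")
        bounded = bool((sm.values >= -1e-12).all() and (sm.values <= 1 + 1e-12).all())
        rep.record(f"{name}_bounded", bounded, "" if bounded else "entries outside [0,1]")
        unit_diag = bool(np.allclose(np.diag(sm.values), 1.0, atol=1e-12))
        rep.record(f"{name}_unit_diagonal", unit_diag, "" if unit_diag else "diagonal != 1")

    if ds.lfs is not None:
        match = ds.lfs.ids == ds.ld.row_ids
        rep.record("LFS_labels_match_LD", match, "" if match else "LFS ids differ from LD rows")
    if ds.dss is not None:
        missing = sorted(set(ds.ld.col_ids) - set(ds.dss.ids))
        rep.record(
            "LD_diseases_in_DSS", not missing,
            "" if not missing else f"diseases missing from DSS, e.g. {missing[:3]}",
        )

    iso_l = [l for i, l in enumerate(ds.ld.row_ids)
             if ds.ld.values[i].sum() == 0 and ds.lm.values[i].sum() == 0]
    rep.record(
        "no_isolated_lncRNAs", not iso_l,
        "" if not iso_l else f"{len(iso_l)} lncRNA(s) without any association, e.g. {iso_l[:3]}",
    )
    return rep
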