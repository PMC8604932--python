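"""Core data types and readers/writers.

Count matrices are dense integer gene-by-cell arrays with ordered gene and
cell identifiers; cell metadata carries the strain and biological-replicate
batch of every cell.  Regulation matrices are directed TF->target edge
tables with a free-text evidence label per edge (Yeastract-style).

On-disk formats:

* MatrixMarket coordinate integer ``matrix.mtx`` plus sidecar ``genes.tsv``
  (column ``gene_id``) and ``cells.tsv`` (columns ``cell_id``, ``strain``,
  ``replicate``) in one directory; genes are rows.
* A dense TSV for small fixtures: header ``gene_id<TAB>cell1<TAB>...``,
  one row per gene.
* Regulation matrix TSV with columns ``regulator``, ``target``,
  ``evidence``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "RegulationMatrix",
    "GeneSet",
    "ParseError",
    "read_count_matrix",
    "write_count_matrix",
    "read_cell_meta",
    "write_cell_meta",
    "validate_cell_meta",
    "read_regulation_matrix",
    "write_regulation_matrix",
    "filter_expressed",
    "restrict_evidence",
]

CELL_META_COLUMNS = ["cell_id", "strain", "replicate"]


class ParseError(ValueError):
    """Raised when an on-disk table violates the format contract."""


@dataclass
class CountMatrix:
    """Gene-by-cell UMI count matrix.

    Parameters
    ----------
    counts
        Non-negative integer array of shape ``(n_genes, n_cells)``.
    gene_ids
        Ordered, unique gene identifiers (rows).
    cell_ids
        Ordered, unique cell identifiers (columns).
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                bad = np.argwhere(self.counts != np.floor(self.counts))[0]
                raise ParseError(
                    f"non-integer count at gene row {bad[0]}, cell column {bad[1]}"
                )
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x cells array")
        if np.any(self.counts < 0):
            bad = np.argwhere(self.counts < 0)[0]
            raise ParseError(f"negative count at gene row {bad[0]}, cell column {bad[1]}")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ParseError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ParseError("duplicate cell identifiers")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown gene identifier {exc.args[0]!r}") from None

    def subset_genes(self, genes) -> "CountMatrix":
        idx = self.gene_index(genes)
        return CountMatrix(self.counts[idx, :], [self.gene_ids[i] for i in idx], list(self.cell_ids))

    def subset_cells(self, cells) -> "CountMatrix":
        lookup = {c: j for j, c in enumerate(self.cell_ids)}
        idx = np.array([lookup[c] for c in cells], dtype=int)
        return CountMatrix(self.counts[:, idx], list(self.gene_ids), [self.cell_ids[j] for j in idx])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and np.array_equal(self.counts, other.counts)
        )


@dataclass
class RegulationMatrix:
    """Directed TF->target edge set with per-edge evidence labels."""

    edges: pd.DataFrame  # columns: regulator, target, evidence

    def __post_init__(self) -> None:
        required = ["regulator", "target", "evidence"]
        missing = [c for c in required if c not in self.edges.columns]
        if missing:
            raise ParseError(f"regulation matrix missing columns: {missing}")
        self.edges = self.edges[required].astype(str).reset_index(drop=True)
        if self.edges.duplicated(["regulator", "target"]).any():
            dup = self.edges[self.edges.duplicated(["regulator", "target"])].iloc[0]
            raise ParseError(
                f"duplicate regulation edge ({dup['regulator']}, {dup['target']})"
            )

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    def targets_of(self, regulator: str) -> set[str]:
        mask = self.edges["regulator"] == regulator
        return set(self.edges.loc[mask, "target"])

    def regulators(self) -> set[str]:
        return set(self.edges["regulator"])

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.members = frozenset(str(g) for g in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def intersection(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}&{other.name}", self.members & other.members)

    def difference(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}-{other.name}", self.members - other.members)

    def union(self, other: "GeneSet", name: str | None = None) -> "GeneSet":
        return GeneSet(name or f"{self.name}|{other.name}", self.members | other.members)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_dense_tsv(path: Path) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected gene_id column plus at least one cell column")
    gene_ids = df.iloc[:, 0].tolist()
    cell_ids = list(df.columns[1:])
    raw = df.iloc[:, 1:].to_numpy()
    counts = np.empty(raw.shape, dtype=np.int64)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            value = raw[i, j]
            try:
                as_float = float(value)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric entry {value!r} at line {i + 2}, column {j + 2}"
                ) from None
            if as_float != int(as_float):
                raise ParseError(
                    f"{path}: non-integer entry {value!r} at line {i + 2}, column {j + 2}"
                )
            counts[i, j] = int(as_float)
    return CountMatrix(counts, gene_ids, cell_ids)


def read_count_matrix(path) -> CountMatrix:
    """Read a count matrix from a MatrixMarket directory or a dense TSV.

    A directory (or a path to a ``.mtx`` file) is interpreted as the
    MatrixMarket dialect with ``genes.tsv``/``cells.tsv`` sidecars; any other
    file is parsed as a dense TSV.
    """
    path = Path(path)
    if path.is_dir() or path.suffix == ".mtx":
        base = path if path.is_dir() else path.parent
        mtx_path = base / "matrix.mtx" if path.is_dir() else path
        for required in (mtx_path, base / "genes.tsv", base / "cells.tsv"):
            if not required.exists():
                raise ParseError(f"missing file {required}")
        mat = scipy.io.mmread(mtx_path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = pd.read_csv(base / "genes.tsv", sep="\t", dtype=str)
        cells = pd.read_csv(base / "cells.tsv", sep="\t", dtype=str)
        if "gene_id" not in genes.columns:
            raise ParseError(f"{base / 'genes.tsv'}: missing gene_id column")
        if "cell_id" not in cells.columns:
            raise ParseError(f"{base / 'cells.tsv'}: missing cell_id column")
        return CountMatrix(mat, genes["gene_id"].tolist(), cells["cell_id"].tolist())
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    return _read_dense_tsv(path)


def write_count_matrix(cm: CountMatrix, path, meta: pd.DataFrame | None = None) -> None:
    """Write a count matrix.

    A path ending in ``.tsv`` produces the dense dialect; anything else is
    treated as a directory and receives ``matrix.mtx`` + sidecars.  ``meta``
    (if given) supplies the strain/replicate columns of ``cells.tsv``.
    """
    path = Path(path)
    if path.suffix == ".tsv":
        df = pd.DataFrame(cm.counts, columns=cm.cell_ids)
        df.insert(0, "gene_id", cm.gene_ids)
        df.to_csv(path, sep="\t", index=False)
        return
    path.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(cm.counts)
    scipy.io.mmwrite(path / "matrix.mtx", sparse, field="integer")
    pd.DataFrame({"gene_id": cm.gene_ids}).to_csv(path / "genes.tsv", sep="\t", index=False)
    if meta is not None:
        validate_cell_meta(meta, cm)
        meta.set_index("cell_id").loc[cm.cell_ids].reset_index().to_csv(
            path / "cells.tsv", sep="\t", index=False
        )
    else:
        pd.DataFrame({"cell_id": cm.cell_ids}).to_csv(path / "cells.tsv", sep="\t", index=False)


def read_cell_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(Path(path), sep="\t", dtype=str)
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: cell metadata missing columns {missing}")
    if meta["cell_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate cell_id in metadata")
    return meta[CELL_META_COLUMNS]


def write_cell_meta(meta: pd.DataFrame, path) -> None:
    meta[CELL_META_COLUMNS].to_csv(Path(path), sep="\t", index=False)


def validate_cell_meta(meta: pd.DataFrame, cm: CountMatrix) -> None:
    """Check every cell of ``cm`` has exactly one metadata row."""
    missing = [c for c in CELL_META_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"cell metadata missing columns {missing}")
    if meta["cell_id"].duplicated().any():
        raise ParseError("duplicate cell_id in metadata")
    absent = set(cm.cell_ids) - set(meta["cell_id"])
    if absent:
        raise ParseError(f"cells without metadata: {sorted(absent)[:5]} ...")


def read_regulation_matrix(path) -> RegulationMatrix:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    return RegulationMatrix(df)


def write_regulation_matrix(rm: RegulationMatrix, path) -> None:
    rm.edges.to_csv(Path(path), sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_expressed(
    cm: CountMatrix,
    meta: pd.DataFrame,
    strain_pair: tuple[str, str],
    min_detect_fraction: float = 0.01,
) -> GeneSet:
    """Genes detected in at least ``min_detect_fraction`` of cells of EACH strain.

    A gene is "detected" in a cell when its count is positive.  Only genes
    passing this filter in both compared strains enter model fitting and
    differential testing for that pair; all others are non-expressed in at
    least one strain and are excluded.
    """
    if not 0.0 <= min_detect_fraction <= 1.0:
        raise ValueError("min_detect_fraction must lie in [0, 1]")
    validate_cell_meta(meta, cm)
    strain_of = dict(zip(meta["cell_id"], meta["strain"]))
    strains = np.array([strain_of[c] for c in cm.cell_ids])
    keep = np.ones(cm.n_genes, dtype=bool)
    for strain in strain_pair:
        mask = strains == strain
        if not mask.any():
            raise ValueError(f"strain {strain!r} has no cells in metadata")
        detected = (cm.counts[:, mask] > 0).mean(axis=1)
        if min_detect_fraction == 0.0:
            keep &= detected > 0.0
        else:
            keep &= detected >= min_detect_fraction
    members = [g for g, k in zip(cm.gene_ids, keep) if k]
    return GeneSet(f"expressed:{strain_pair[0]}~{strain_pair[1]}", members)


def restrict_evidence(rm: RegulationMatrix, allowed) -> RegulationMatrix:
    """Keep only edges whose evidence label is in ``allowed``; never adds edges."""
    allowed = set(allowed)
    kept = rm.edges[rm.edges["evidence"].isin(allowed)].reset_index(drop=True)
    return RegulationMatrix(kept)
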