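"""Count-matrix containers and readers/writers for standard on-disk formats.

Counts live in a :class:`CountMatrix` -- genes as rows, cells as columns,
stored sparsely (CSR) because UMI matrices are typically >85% zeros.  Two
readers cover the common distribution formats: the 10x Genomics Matrix
Market triplet directory (both the v2 ``genes.tsv`` and v3
``features.tsv.gz`` layouts) and plain delimited tables.  Result tables are
written as TSV with full double precision so that a round trip is lossless.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """A gene x cell matrix of non-negative integer counts.

    Parameters
    ----------
    values
        Dense or sparse matrix, genes in rows, cells in columns. Stored
        internally as CSR with explicit zeros removed.
    gene_ids, cell_ids
        Unique row and column identifiers.
    """

    values: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]

    def __post_init__(self) -> None:
        values = self.values
        if not sp.issparse(values):
            values = sp.csr_matrix(np.asarray(values))
        values = values.tocsr()
        values.eliminate_zeros()
        if values.nnz and values.data.min() < 0:
            raise ValidationError("counts must be non-negative")
        if values.nnz and np.any(values.data != np.round(values.data)):
            raise ValidationError("counts must be integral")
        self.values = values.astype(np.int64)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.gene_ids) != values.shape[0]:
            raise ValidationError(
                f"{len(self.gene_ids)} gene ids for {values.shape[0]} rows"
            )
        if len(self.cell_ids) != values.shape[1]:
            raise ValidationError(
                f"{len(self.cell_ids)} cell ids for {values.shape[1]} columns"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def density(self) -> float:
        return self.values.nnz / (self.n_genes * self.n_cells)

    def subset_cells(self, index: Sequence[int]) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(
            self.values.tocsc()[:, index].tocsr(),
            list(self.gene_ids),
            [self.cell_ids[i] for i in index],
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class GroupLabels:
    """Per-cell assignment to one of two groups, coded 1 and 2."""

    assignment: np.ndarray
    cell_ids: list[str] | None = None
    level_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int8)
        if not np.isin(self.assignment, (1, 2)).all():
            raise ValidationError("group assignment must be coded 1 or 2")
        if self.n1 < 1 or self.n2 < 1:
            raise ValidationError("both groups need at least one cell")
        if self.cell_ids is not None and len(self.cell_ids) != self.assignment.size:
            raise ValidationError("cell_ids length does not match assignment")

    @property
    def n1(self) -> int:
        return int(np.sum(self.assignment == 1))

    @property
    def n2(self) -> int:
        return int(np.sum(self.assignment == 2))

    @property
    def n_cells(self) -> int:
        return self.assignment.size

    def indices(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == group)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _find_file(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for name in (stem, stem + ".gz"):
            candidate = directory / name
            if candidate.is_file():
                return candidate
    raise FormatError(
        f"none of {', '.join(stems)} (or .gz variants) found in {directory}"
    )


def _read_id_column(path: Path, column: int = 0) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    ids = []
    with opener(path, "rt") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            ids.append(parts[min(column, len(parts) - 1)])
    return ids


def read_counts_mtx(path: str | Path) -> CountMatrix:
    """Read a 10x-style Matrix Market triplet directory.

    Accepts both the v2 layout (``matrix.mtx``, ``genes.tsv``,
    ``barcodes.tsv``) and the v3 layout (gzipped, ``features.tsv.gz``),
    auto-detected.  Genes end up in rows regardless of the on-disk
    orientation, decided by matching axis lengths against the id files.
    """
    directory = Path(path)
    if not directory.is_dir():
        raise FormatError(f"{directory} is not a directory")
    matrix_path = _find_file(directory, ["matrix.mtx"])
    genes_path = _find_file(directory, ["genes.tsv", "features.tsv"])
    barcodes_path = _find_file(directory, ["barcodes.tsv"])

    gene_ids = _read_id_column(genes_path)
    cell_ids = _read_id_column(barcodes_path)
    try:
        matrix = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy error text varies
        raise FormatError(f"could not parse {matrix_path}: {exc}") from exc
    matrix = sp.coo_matrix(matrix)

    if matrix.shape == (len(gene_ids), len(cell_ids)):
        pass
    elif matrix.shape == (len(cell_ids), len(gene_ids)) and matrix.shape[0] != matrix.shape[1]:
        matrix = matrix.T
    else:
        raise FormatError(
            f"matrix shape {matrix.shape} matches neither "
            f"{len(gene_ids)} genes x {len(cell_ids)} cells nor its transpose"
        )
    return CountMatrix(matrix.tocsr(), gene_ids, cell_ids)


def read_counts_table(path: str | Path, genes_in: str = "rows") -> CountMatrix:
    """Read a delimited count table with a header row and an id first column.

    ``genes_in`` says which axis holds genes on disk; the returned matrix
    always has genes in rows.
    """
    if genes_in not in ("rows", "columns"):
        raise ValidationError("genes_in must be 'rows' or 'columns'")
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    except Exception as exc:
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if frame.index.has_duplicates:
        raise ValidationError(f"duplicate ids in first column of {path}")
    if frame.columns.has_duplicates:
        raise ValidationError(f"duplicate ids in header of {path}")
    if genes_in == "columns":
        frame = frame.T
    values = frame.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"non-numeric entries in {path}")
    return CountMatrix(
        sp.csr_matrix(values), list(frame.index.astype(str)), list(frame.columns.astype(str))
    )


def read_group_labels(
    path: str | Path, counts: CountMatrix
) -> tuple[CountMatrix, GroupLabels]:
    """Read a two-column TSV (cell_id, group) and align it with ``counts``.

    Cells present in the matrix but absent from the label file are dropped
    with a warning; labelled cells missing from the matrix raise.  Any two
    distinct label values are accepted and mapped to groups 1 and 2 in
    sorted order.
    """
    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    table = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if table.shape[1] < 2:
        raise FormatError(f"{path} needs two columns: cell_id and group")
    # tolerate an optional header line
    if table.iloc[0, 0].lower() in ("cell_id", "cell", "barcode"):
        table = table.iloc[1:]
    mapping = dict(zip(table.iloc[:, 0], table.iloc[:, 1]))
    unknown = set(mapping) - set(counts.cell_ids)
    if unknown:
        raise ValidationError(
            f"{len(unknown)} labelled cells not present in the count matrix "
            f"(e.g. {sorted(unknown)[:3]})"
        )
    keep = [i for i, c in enumerate(counts.cell_ids) if c in mapping]
    dropped = counts.n_cells - len(keep)
    if dropped:
        logger.warning("dropping %d cells without a group label", dropped)
        counts = counts.subset_cells(keep)
    levels = sorted(set(mapping.values()))
    if len(levels) != 2:
        raise ValidationError(f"expected exactly 2 group levels, got {levels}")
    code = {levels[0]: 1, levels[1]: 2}
    assignment = np.array([code[mapping[c]] for c in counts.cell_ids], dtype=np.int8)
    labels = GroupLabels(
        assignment, cell_ids=list(counts.cell_ids), level_names={1: levels[0], 2: levels[1]}
    )
    return counts, labels


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

RESULT_COLUMNS = ["gene_id", "m1", "m2", "L1", "L2", "L3", "Q", "p", "q", "is_de"]


def write_results(results, path: str | Path) -> None:
    """Write a result table as TSV, losslessly for doubles.

    The fitted degrees of freedom and the FDR level ride along as ``#``
    comment lines so a written file is self-describing.
    """
    path = Path(path)
    frame = results.frame.loc[:, RESULT_COLUMNS]
    with open(path, "w") as handle:
        handle.write(f"# fitted_df={results.fitted_df!r}\n")
        handle.write(f"# alpha={results.alpha!r}\n")
        frame.to_csv(handle, sep="\t", index=False, float_format="%.17g")


def read_results(path: str | Path):
    """Read a TSV written by :func:`write_results` back into a result table."""
    from .model import HeartResultTable  # local import to avoid a cycle

    path = Path(path)
    if not path.is_file():
        raise FormatError(f"no such file: {path}")
    meta = {}
    with open(path) as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
    frame = pd.read_csv(path, sep="\t", comment="#")
    frame["gene_id"] = frame["gene_id"].astype(str)
    frame["is_de"] = frame["is_de"].astype(bool)
    return HeartResultTable(
        frame=frame,
        fitted_df=meta.get("fitted_df", float("nan")),
        alpha=meta.get("alpha", 0.05),
    )


def write_counts_mtx(counts: CountMatrix, directory: str | Path) -> None:
    """Write a CountMatrix as an uncompressed 10x v2-style triplet directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), counts.values.tocoo(), field="integer")
    (directory / "genes.tsv").write_text(
        "".join(f"{g}\t{g}\n" for g in counts.gene_ids)
    )
    (directory / "barcodes.tsv").write_text("".join(f"{c}\n" for c in counts.cell_ids))


def write_group_labels(labels: GroupLabels, path: str | Path) -> None:
    """Write labels as a two-column TSV readable by :func:`read_group_labels`."""
    if labels.cell_ids is None:
        raise ValidationError("labels carry no cell ids; cannot write a label file")
    with open(path, "w") as handle:
        for cell, grp in zip(labels.cell_ids, labels.assignment):
            name = labels.level_names.get(int(grp), str(grp))
            handle.write(f"{cell}\t{name}\n")
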