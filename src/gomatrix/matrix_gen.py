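"""Gene × GO-class binary membership matrices.

Rows are genes in input order; columns are every GO class occurring in
any closed annotation set (direct terms plus propagated ancestors),
ordered by numeric accession.  The native serialization is the
three-column sparse triplet layout — row index, column index, value —
with row and column name registries in separate files, all 1-based so
the files load directly into R or Matlab.  A dense TSV grid and a
MatrixMarket writer are provided as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO

from .annotation_io import AnnotationSet
from .errors import GomatrixError
from .obo_model import split_accession


@dataclass
class MembershipMatrix:
    """Binary membership matrix as named sparse cells.

    ``cells`` holds 1-based (row, column) pairs, each meaning value 1.
    """

    row_names: list[str] = field(default_factory=list)
    col_names: list[str] = field(default_factory=list)
    cells: set[tuple[int, int]] = field(default_factory=set)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.row_names), len(self.col_names)

    def row_sums(self) -> list[int]:
        sums = [0] * len(self.row_names)
        for r, _ in self.cells:
            sums[r - 1] += 1
        return sums

    def col_sums(self) -> list[int]:
        sums = [0] * len(self.col_names)
        for _, c in self.cells:
            sums[c - 1] += 1
        return sums

    def to_scipy(self):
        """Materialize as a scipy.sparse CSR matrix (int8)."""
        import numpy as np
        from scipy import sparse

        rows = np.fromiter((r - 1 for r, _ in self.cells), dtype=np.int64,
                           count=len(self.cells))
        cols = np.fromiter((c - 1 for _, c in self.cells), dtype=np.int64,
                           count=len(self.cells))
        data = np.ones(len(self.cells), dtype=np.int8)
        return sparse.coo_matrix(
            (data, (rows, cols)), shape=self.shape
        ).tocsr()


def build_matrix(closed: AnnotationSet) -> MembershipMatrix:
    """Build the membership matrix from a closed annotation set.

    Column set is exactly the union of all closed terms, sorted by
    numeric key; row order is record order.  Genes with empty closures
    keep their row (all zeros) so matrix dimensions are stable.

    Raises :class:`GomatrixError` when no gene has a nonempty closure.
    """
    all_terms: set[str] = set()
    for _, terms in closed.records:
        all_terms.update(terms)
    if not all_terms:
        raise GomatrixError("no gene has a nonempty closed term set")
    col_names = sorted(all_terms, key=lambda a: split_accession(a)[1])
    col_index = {a: i + 1 for i, a in enumerate(col_names)}
    row_names = [g for g, _ in closed.records]
    cells = {
        (r + 1, col_index[a])
        for r, (_, terms) in enumerate(closed.records)
        for a in terms
    }
    return MembershipMatrix(row_names=row_names, col_names=col_names, cells=cells)


def write_sparse(
    matrix: MembershipMatrix,
    triplet_stream: IO[str],
    rownames_stream: IO[str],
    colnames_stream: IO[str],
) -> None:
    """Write the triplet file plus the two name registries.

    Triplets are ``row<TAB>col<TAB>1``, sorted by (row, col); name files
    hold one name per line, the line number being the 1-based index.
    """
    for r, c in sorted(matrix.cells):
        triplet_stream.write(f"{r}\t{c}\t1\n")
    for name in matrix.row_names:
        rownames_stream.write(f"{name}\n")
    for name in matrix.col_names:
        colnames_stream.write(f"{name}\n")


def read_sparse(
    triplet_stream: IO[str],
    rownames_stream: IO[str],
    colnames_stream: IO[str],
) -> MembershipMatrix:
    """Inverse of :func:`write_sparse`.

    Rejects out-of-range indices, non-1 values, and duplicate cells.
    """
    row_names = [line.rstrip("\r\n") for line in rownames_stream if line.strip()]
    col_names = [line.rstrip("\r\n") for line in colnames_stream if line.strip()]
    if not row_names or not col_names:
        raise GomatrixError("empty row or column name registry")
    cells: set[tuple[int, int]] = set()
    for lineno, raw in enumerate(triplet_stream, start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise GomatrixError(f"triplet line {lineno}: expected 3 fields")
        r, c, v = (int(p) for p in parts)
        if v != 1:
            raise GomatrixError(f"triplet line {lineno}: value must be 1, got {v}")
        if not (1 <= r <= len(row_names) and 1 <= c <= len(col_names)):
            raise GomatrixError(f"triplet line {lineno}: index ({r},{c}) out of range")
        if (r, c) in cells:
            raise GomatrixError(f"triplet line {lineno}: duplicate cell ({r},{c})")
        cells.add((r, c))
    return MembershipMatrix(row_names=row_names, col_names=col_names, cells=cells)


def write_full(matrix: MembershipMatrix, stream: IO[str]) -> None:
    """Write the dense 0/1 TSV grid.

    Header row is an empty corner cell followed by the column names;
    every data row is the gene id followed by explicit 0/1 fields.
    """
    stream.write("\t" + "\t".join(matrix.col_names) + "\n")
    ncol = len(matrix.col_names)
    by_row: dict[int, set[int]] = {}
    for r, c in matrix.cells:
        by_row.setdefault(r, set()).add(c)
    for r, gene in enumerate(matrix.row_names, start=1):
        hit = by_row.get(r, ())
        row = ["1" if c in hit else "0" for c in range(1, ncol + 1)]
        stream.write(gene + "\t" + "\t".join(row) + "\n")


def read_full(stream: IO[str]) -> MembershipMatrix:
    """Read a grid written by :func:`write_full` (for cross-format checks)."""
    header = next(iter(stream)).rstrip("\r\n").split("\t")
    col_names = header[1:]
    row_names: list[str] = []
    cells: set[tuple[int, int]] = set()
    for raw in stream:
        fields = raw.rstrip("\r\n").split("\t")
        if len(fields) != len(col_names) + 1:
            raise GomatrixError("dense row width does not match header")
        row_names.append(fields[0])
        r = len(row_names)
        for c, v in enumerate(fields[1:], start=1):
            if v == "1":
                cells.add((r, c))
            elif v != "0":
                raise GomatrixError(f"dense cell must be 0 or 1, got {v!r}")
    return MembershipMatrix(row_names=row_names, col_names=col_names, cells=cells)


def write_mtx(matrix: MembershipMatrix, stream: IO[str]) -> None:
    """Optional MatrixMarket coordinate output for direct scipy/R import."""
    stream.write("%%MatrixMarket matrix coordinate integer general\n")
    stream.write(f"{len(matrix.row_names)} {len(matrix.col_names)} {len(matrix.cells)}\n")
    for r, c in sorted(matrix.cells):
        stream.write(f"{r} {c} 1\n")
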