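"""Reading gene→GO annotation inputs and writing the augmented listing.

Two input dialects are supported: a generic TAB-separated table where the
user names the gene column and the GO column(s), and GAF 2.x association
files (DB object id in column 2, GO id in column 5, ``NOT`` qualifier
lines skipped).  Both normalize to an :class:`AnnotationSet` — an ordered
list of (gene, direct GO terms) records in first-occurrence order, with
duplicate genes merged by term-set union.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import AnnotationFormatError
from .obo_model import ACCESSION_RE, split_accession

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """Ordered gene → direct-GO-term mapping.

    ``records`` preserves first-occurrence gene order; each term tuple
    preserves first-seen order (or numeric order once closed).
    """

    records: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)
    source_dialect: str = "generic_tsv"

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ParseCounts:
    """Bookkeeping from one annotation parse."""

    n_rows: int = 0
    n_skipped_rows: int = 0
    n_malformed_tokens: int = 0
    n_not_qualified: int = 0
    n_dropped_genes: int = 0


def _looks_like_accession(token: str) -> bool:
    return bool(ACCESSION_RE.match(token))


def parse_generic(
    stream: IO[str] | Iterable[str],
    gene_col: int,
    go_cols: list[int],
    go_separator: str = ";",
    header: bool | None = None,
) -> tuple[AnnotationSet, ParseCounts]:
    """Parse a generic TAB-separated annotation table.

    Column indices are 1-based (the convention annotation tools present
    to users).  Cells in ``go_cols`` may hold several accessions joined
    by ``go_separator``; tokens not matching ``prefix:digits`` are
    counted as malformed and dropped.  Rows too short for the requested
    columns are skipped with a warning.  ``header=None`` auto-detects a
    header row (first row whose GO columns contain no valid accession);
    True/False forces the behaviour.

    Raises :class:`AnnotationFormatError` if no valid data rows remain.
    """
    if gene_col < 1 or any(c < 1 for c in go_cols):
        raise AnnotationFormatError("column indices are 1-based; got a value < 1")
    if gene_col in go_cols:
        raise AnnotationFormatError(
            f"gene column {gene_col} also listed as a GO column"
        )
    counts = ParseCounts()
    need = max([gene_col, *go_cols])
    order: list[str] = []
    table: dict[str, dict[str, None]] = {}
    first_data_row = True
    for raw in stream:
        line = raw.rstrip("\r\n")
        if not line:
            continue
        fields = line.split("\t")
        counts.n_rows += 1
        if len(fields) < need:
            counts.n_skipped_rows += 1
            logger.warning("row %d has %d columns, need %d; skipped",
                           counts.n_rows, len(fields), need)
            continue
        gene = fields[gene_col - 1].strip()
        tokens: list[str] = []
        n_bad = 0
        for c in go_cols:
            cell = fields[c - 1]
            for token in cell.split(go_separator):
                token = token.strip()
                if not token:
                    continue
                if _looks_like_accession(token):
                    tokens.append(token)
                else:
                    n_bad += 1
        if first_data_row:
            is_header = header if header is not None else not tokens
            first_data_row = False
            if is_header:
                counts.n_rows -= 1
                continue
        counts.n_malformed_tokens += n_bad
        if not gene:
            counts.n_skipped_rows += 1
            continue
        if not tokens:
            counts.n_dropped_genes += 1
            logger.warning("gene %r has no valid GO tokens; dropped", gene)
            continue
        if gene not in table:
            table[gene] = {}
            order.append(gene)
        for t in tokens:
            table[gene][t] = None
    if not order:
        raise AnnotationFormatError("no valid annotation rows in input")
    records = [(g, tuple(table[g])) for g in order]
    return AnnotationSet(records=records, source_dialect="generic_tsv"), counts


GAF_MIN_COLUMNS = 15


def parse_gaf(stream: IO[str] | Iterable[str]) -> tuple[AnnotationSet, ParseCounts]:
    """Parse a GAF 2.x gene association file.

    Comment lines start with ``!``; each association line contributes one
    term to its DB-object (column 2), except lines whose qualifier
    (column 4) contains ``NOT``, which are skipped and counted.
    """
    counts = ParseCounts()
    order: list[str] = []
    table: dict[str, dict[str, None]] = {}
    for raw in stream:
        line = raw.rstrip("\r\n")
        if not line or line.startswith("!"):
            continue
        fields = line.split("\t")
        counts.n_rows += 1
        if len(fields) < GAF_MIN_COLUMNS:
            counts.n_skipped_rows += 1
            logger.warning("GAF line with %d columns skipped", len(fields))
            continue
        qualifier = fields[3]
        if "NOT" in qualifier.split("|"):
            counts.n_not_qualified += 1
            continue
        gene = fields[1].strip()
        term = fields[4].strip()
        if not gene:
            counts.n_skipped_rows += 1
            continue
        if not _looks_like_accession(term):
            counts.n_malformed_tokens += 1
            continue
        if gene not in table:
            table[gene] = {}
            order.append(gene)
        table[gene][term] = None
    if not order:
        raise AnnotationFormatError("no usable association lines in GAF input")
    records = [(g, tuple(table[g])) for g in order]
    return AnnotationSet(records=records, source_dialect="gaf"), counts


def write_augmented(closed: AnnotationSet, stream: IO[str]) -> None:
    """Write the per-gene augmented listing.

    One TAB-separated row per gene: the gene id, then all closed
    accessions sorted by numeric key and joined by ``;`` in a single
    second column.  Genes whose closure came out empty keep their row
    with an empty second field.  Output is byte-deterministic.
    """
    for gene_id, terms in closed.records:
        ordered = sorted(terms, key=lambda a: split_accession(a)[1])
        stream.write(f"{gene_id}\t{';'.join(ordered)}\n")
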