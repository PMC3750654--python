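"""In-memory model of an OBO 1.2 ontology.

An ontology flat file is parsed into a table of :class:`OntologyTerm`
records keyed by the numeric part of the accession (``GO:0008150`` ->
``8150``), mirroring how GO tools index terms for O(1) lookup.  Parent
structure is restricted to the two propagating relations, ``is_a`` and
``relationship: part_of``; ``consider`` and ``replaced_by`` are kept as
resolution hints for obsolete classes and never act as graph edges.

:func:`resolve_term` maps *any* incoming accession — current primary id,
merged alt_id, or obsolete id — onto the live primary term(s) it stands
for, which is the lookup annotation pipelines need before propagating.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import CycleError, InvalidAccessionError, OboFormatError

logger = logging.getLogger(__name__)

ACCESSION_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*):(\d+)$")

#: replaced_by chains longer than this are treated as unresolvable
#: (guards against malformed or circular replacement data).
MAX_REPLACEMENT_DEPTH = 5


def split_accession(accession: str) -> tuple[str, int]:
    """Split ``prefix:digits`` into ``(prefix, numeric_key)``.

    Raises :class:`InvalidAccessionError` for anything else.
    """
    m = ACCESSION_RE.match(accession.strip())
    if not m:
        raise InvalidAccessionError(f"not a prefix:digits accession: {accession!r}")
    return m.group(1), int(m.group(2))


@dataclass
class OntologyTerm:
    """One ontology class with its parsed OBO attributes.

    ``numeric_key`` is the integer value of the digit part of ``go_id``;
    ``go_id`` keeps the original prefix and zero padding so non-GO
    ontologies (e.g. Plant Ontology ``PO:`` accessions) round-trip.
    """

    numeric_key: int
    go_id: str
    name: str = ""
    namespace: str = "other"
    definition: str = ""
    is_obsolete: bool = False
    is_a_parents: list[int] = field(default_factory=list)
    part_of_parents: list[int] = field(default_factory=list)
    consider_targets: list[int] = field(default_factory=list)
    replaced_by: int | None = None
    alt_ids: list[str] = field(default_factory=list)

    @property
    def parents(self) -> list[int]:
        """is_a and part_of parents, in file order (is_a first)."""
        return self.is_a_parents + self.part_of_parents


@dataclass
class Ontology:
    """Term table plus the alt_id index and header metadata."""

    terms: dict[int, OntologyTerm] = field(default_factory=dict)
    alt_index: dict[str, int] = field(default_factory=dict)
    source_date: str | None = None
    format_version: str = ""

    def __len__(self) -> int:
        return len(self.terms)

    def live_keys(self) -> list[int]:
        return [k for k, t in self.terms.items() if not t.is_obsolete]

    def n_edges(self) -> int:
        return sum(len(t.parents) for t in self.terms.values() if not t.is_obsolete)


@dataclass(frozen=True)
class Resolution:
    """Outcome of resolving one accession.

    ``status`` is one of ``primary``, ``alt_id``, ``obsolete_replaced``,
    ``obsolete_consider``, ``unknown``; ``targets`` holds the numeric keys
    of live primary terms (empty iff unknown, length > 1 only for
    ``obsolete_consider``).
    """

    status: str
    targets: tuple[int, ...]


_VALID_NAMESPACES = {"biological_process", "molecular_function", "cellular_component"}


def _parse_header(lines: list[str]) -> tuple[str, str | None]:
    fmt, date = "", None
    for line in lines:
        if line.startswith("format-version:"):
            fmt = line.split(":", 1)[1].strip()
        elif line.startswith("date:"):
            date = line.split(":", 1)[1].strip()
    return fmt, date


def _strip_comment(value: str) -> str:
    # "GO:0008150 ! biological_process" -> "GO:0008150"
    return value.split("!", 1)[0].strip()


def parse_obo(stream: IO[str] | Iterable[str]) -> Ontology:
    """Parse OBO 1.2 text into an :class:`Ontology`.

    Only ``[Term]`` stanzas are consumed; other stanza types are skipped
    with a debug log line.  Handled tags: id, name, namespace, def,
    is_obsolete, alt_id, is_a, relationship (part_of only), consider,
    replaced_by.  Everything else is ignored.

    Raises :class:`OboFormatError` for duplicate primary ids, stanzas
    without an id line, or dangling parent references, and
    :class:`CycleError` if the is_a/part_of graph has a cycle.
    """
    ontology = Ontology()
    header_lines: list[str] = []
    in_header = True
    current: dict | None = None
    current_type: str | None = None
    stanza_offset = 0
    offset = 0
    # raw parent accessions kept until all stanzas are read, so forward
    # references within the file are legal
    pending: list[tuple[dict, str]] = []

    def finish_stanza() -> None:
        nonlocal current
        if current is None or current_type != "Term":
            current = None
            return
        if "id" not in current:
            raise OboFormatError("[Term] stanza without an id line", offset=stanza_offset)
        prefix, key = split_accession(current["id"])
        if key in ontology.terms:
            raise OboFormatError(
                f"duplicate primary id {current['id']}", offset=stanza_offset
            )
        term = OntologyTerm(
            numeric_key=key,
            go_id=current["id"],
            name=current.get("name", ""),
            namespace=current.get("namespace", "other"),
            definition=current.get("def", ""),
            is_obsolete=current.get("is_obsolete", False),
            alt_ids=current.get("alt_ids", []),
        )
        ontology.terms[key] = term
        pending.append((current, "placeholder"))
        current["_term"] = term
        current = None

    for raw in stream:
        line = raw.rstrip("\r\n")
        line_bytes = len(raw.encode("utf-8"))
        if line.startswith("["):
            in_header = False
            finish_stanza()
            stanza_offset = offset
            stanza_type = line.strip().strip("[]")
            if stanza_type == "Term":
                current_type = "Term"
                current = {
                    "_offset": stanza_offset,
                    "is_a_raw": [],
                    "part_of_raw": [],
                    "consider_raw": [],
                    "alt_ids": [],
                }
            else:
                logger.debug("skipping [%s] stanza at byte offset %d", stanza_type, offset)
                current_type = stanza_type
                current = None
            offset += line_bytes
            continue
        if in_header:
            header_lines.append(line)
            offset += line_bytes
            continue
        if current is not None and ":" in line:
            tag, value = line.split(":", 1)
            tag = tag.strip()
            value = value.strip()
            if tag == "id":
                current["id"] = _strip_comment(value)
            elif tag == "name":
                current["name"] = value
            elif tag == "namespace":
                current["namespace"] = value
            elif tag == "def":
                current["def"] = value
            elif tag == "is_obsolete":
                current["is_obsolete"] = value.lower().startswith("true")
            elif tag == "alt_id":
                current["alt_ids"].append(_strip_comment(value))
            elif tag == "is_a":
                current["is_a_raw"].append(_strip_comment(value))
            elif tag == "relationship":
                parts = _strip_comment(value).split()
                if len(parts) == 2 and parts[0] == "part_of":
                    current["part_of_raw"].append(parts[1])
                # regulates, has_part, ... are not propagating relations
            elif tag == "consider":
                current["consider_raw"].append(_strip_comment(value))
            elif tag == "replaced_by":
                current["replaced_by_raw"] = _strip_comment(value)
        offset += line_bytes
    finish_stanza()

    ontology.format_version, ontology.source_date = _parse_header(header_lines)

    # second pass: wire edges now that the whole term table exists
    for stanza, _ in pending:
        term: OntologyTerm = stanza["_term"]
        for acc in stanza["is_a_raw"]:
            _, pk = split_accession(acc)
            if pk not in ontology.terms:
                raise OboFormatError(
                    f"{term.go_id}: dangling is_a reference {acc}",
                    offset=stanza["_offset"],
                )
            term.is_a_parents.append(pk)
        for acc in stanza["part_of_raw"]:
            _, pk = split_accession(acc)
            if pk not in ontology.terms:
                raise OboFormatError(
                    f"{term.go_id}: dangling part_of reference {acc}",
                    offset=stanza["_offset"],
                )
            term.part_of_parents.append(pk)
        for acc in stanza["consider_raw"]:
            _, ck = split_accession(acc)
            term.consider_targets.append(ck)
        if "replaced_by_raw" in stanza:
            _, rk = split_accession(stanza["replaced_by_raw"])
            term.replaced_by = rk
        if (term.consider_targets or term.replaced_by is not None) and not term.is_obsolete:
            # retained but never traversed for live terms
            logger.warning(
                "%s carries consider/replaced_by but is not obsolete", term.go_id
            )
        for alt in term.alt_ids:
            _, ak = split_accession(alt)
            if alt in ontology.alt_index:
                logger.warning(
                    "alt_id %s claimed by %s and %s; first wins",
                    alt,
                    ontology.terms[ontology.alt_index[alt]].go_id,
                    term.go_id,
                )
            elif ak in ontology.terms:
                logger.warning(
                    "alt_id %s of %s shadows a primary id; primary wins",
                    alt, term.go_id,
                )
            else:
                ontology.alt_index[alt] = term.numeric_key

    _check_acyclic(ontology)
    return ontology


def _check_acyclic(ontology: Ontology) -> None:
    """Iterative three-colour DFS over is_a ∪ part_of; raises CycleError."""
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {k: WHITE for k in ontology.terms}
    for start in ontology.terms:
        if colour[start] != WHITE:
            continue
        stack: list[tuple[int, iter]] = [(start, iter(ontology.terms[start].parents))]
        colour[start] = GREY
        path = [start]
        while stack:
            node, it = stack[-1]
            advanced = False
            for parent in it:
                if colour[parent] == GREY:
                    i = path.index(parent)
                    raise CycleError(path[i:] + [parent])
                if colour[parent] == WHITE:
                    colour[parent] = GREY
                    path.append(parent)
                    stack.append((parent, iter(ontology.terms[parent].parents)))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                path.pop()
                stack.pop()


def resolve_term(
    ontology: Ontology, accession: str, resolve_obsolete: bool = True
) -> Resolution:
    """Resolve an accession to live primary term(s).

    Lookup order: primary id, then alt_id index, then — for obsolete
    primaries, when ``resolve_obsolete`` — replaced_by (chains followed up
    to :data:`MAX_REPLACEMENT_DEPTH`) and finally consider targets.  A
    syntactically invalid accession raises
    :class:`InvalidAccessionError`; a valid-but-unregistered one returns
    status ``unknown``.
    """
    acc = accession.strip()
    _, key = split_accession(acc)

    status_hint: str | None = None
    if key in ontology.terms:
        term = ontology.terms[key]
    elif acc in ontology.alt_index:
        term = ontology.terms[ontology.alt_index[acc]]
        status_hint = "alt_id"
    else:
        return Resolution("unknown", ())

    if not term.is_obsolete:
        if status_hint == "alt_id":
            return Resolution("alt_id", (term.numeric_key,))
        return Resolution("primary", (term.numeric_key,))

    if not resolve_obsolete:
        return Resolution("unknown", ())

    live = _follow_replacement(ontology, term)
    if live is not None:
        return Resolution("obsolete_replaced", (live,))
    targets = []
    for ck in term.consider_targets:
        if ck in ontology.terms:
            ct = ontology.terms[ck]
            if not ct.is_obsolete:
                targets.append(ck)
            else:
                deep = _follow_replacement(ontology, ct)
                if deep is not None:
                    targets.append(deep)
    if targets:
        # preserve order, drop duplicates
        seen: dict[int, None] = dict.fromkeys(targets)
        return Resolution("obsolete_consider", tuple(seen))
    return Resolution("unknown", ())


def _follow_replacement(ontology: Ontology, term: OntologyTerm) -> int | None:
    """Walk replaced_by links to a live term; None if the chain dead-ends
    or exceeds the depth cap."""
    depth = 0
    while term.replaced_by is not None and depth < MAX_REPLACEMENT_DEPTH:
        nxt = ontology.terms.get(term.replaced_by)
        if nxt is None:
            return None
        if not nxt.is_obsolete:
            return nxt.numeric_key
        term = nxt
        depth += 1
    return None


def serialize_obo(ontology: Ontology, stream: IO[str]) -> None:
    """Write the ontology back out as OBO 1.2 text.

    Tag order within a stanza is fixed (id, name, namespace, alt_id*,
    def, is_a*, relationship*, is_obsolete, replaced_by, consider*) so
    serialization is byte-deterministic; terms are emitted in numeric-key
    order.
    """
    if ontology.format_version:
        stream.write(f"format-version: {ontology.format_version}\n")
    if ontology.source_date:
        stream.write(f"date: {ontology.source_date}\n")
    stream.write("\n")

    def acc_of(key: int) -> str:
        return ontology.terms[key].go_id

    for key in sorted(ontology.terms):
        t = ontology.terms[key]
        stream.write("[Term]\n")
        stream.write(f"id: {t.go_id}\n")
        stream.write(f"name: {t.name}\n")
        stream.write(f"namespace: {t.namespace}\n")
        for alt in t.alt_ids:
            stream.write(f"alt_id: {alt}\n")
        if t.definition:
            stream.write(f"def: {t.definition}\n")
        for pk in t.is_a_parents:
            stream.write(f"is_a: {acc_of(pk)}\n")
        for pk in t.part_of_parents:
            stream.write(f"relationship: part_of {acc_of(pk)}\n")
        if t.is_obsolete:
            stream.write("is_obsolete: true\n")
        if t.replaced_by is not None:
            prefix = t.go_id.split(":", 1)[0]
            width = len(t.go_id.split(":", 1)[1])
            stream.write(f"replaced_by: {prefix}:{t.replaced_by:0{width}d}\n")
        for ck in t.consider_targets:
            prefix = t.go_id.split(":", 1)[0]
            width = len(t.go_id.split(":", 1)[1])
            stream.write(f"consider: {prefix}:{ck:0{width}d}\n")
        stream.write("\n")
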