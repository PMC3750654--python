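"""Ancestor closure over the ontology DAG with a dynamically grown memo.

Annotation to a term implies annotation to every is_a/part_of ancestor
(the true-path rule).  :class:`ClosureCache` memoizes the closure of each
term as it is first needed, so processing a whole annotation file costs
one traversal of each ontology edge regardless of how many genes repeat
the same terms — the cache can never grow beyond the term table itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .annotation_io import AnnotationSet
from .errors import GomatrixError
from .obo_model import Ontology, Resolution, resolve_term, split_accession


@dataclass
class ClosureCache:
    """Memo table: numeric key -> frozenset of the term plus all ancestors.

    ``edge_traversals`` counts parent-link visits; with a shared cache it
    is bounded by the ontology's live edge count, which is what makes the
    pipeline's cost independent of gene count.
    """

    memo: dict[int, frozenset[int]] = field(default_factory=dict)
    edge_traversals: int = 0

    def __len__(self) -> int:
        return len(self.memo)


def ancestors(
    ontology: Ontology, key: int, cache: ClosureCache | None = None
) -> frozenset[int]:
    """Return ``{key} ∪ all is_a/part_of ancestors`` of a live term.

    Iterative post-order so ontology depth cannot overflow the call
    stack; every term finished on the way up is cached, so later queries
    for any ancestor are O(1).  Obsolete ancestors (which a malformed
    file could introduce) are excluded from results.

    Raises :class:`GomatrixError` if ``key`` is absent or obsolete —
    callers must resolve accessions first.
    """
    term = ontology.terms.get(key)
    if term is None:
        raise GomatrixError(f"unknown term key {key}; resolve accessions first")
    if term.is_obsolete:
        raise GomatrixError(f"term key {key} is obsolete; resolve it first")
    if cache is None:
        cache = ClosureCache()
    if key in cache.memo:
        return cache.memo[key]

    # explicit DFS stack; a node is finalized once all parents are cached
    stack = [key]
    while stack:
        node = stack[-1]
        if node in cache.memo:
            stack.pop()
            continue
        missing = []
        for parent in ontology.terms[node].parents:
            if parent not in cache.memo and not ontology.terms[parent].is_obsolete:
                missing.append(parent)
        if missing:
            stack.extend(missing)
            continue
        closed = {node}
        for parent in ontology.terms[node].parents:
            cache.edge_traversals += 1
            if ontology.terms[parent].is_obsolete:
                continue
            closed.update(cache.memo[parent])
        cache.memo[node] = frozenset(closed)
        stack.pop()
    return cache.memo[key]


@dataclass
class ClosureSummary:
    """Bookkeeping from closing one annotation set."""

    n_genes: int = 0
    n_direct_terms: int = 0
    n_unresolved: int = 0
    n_obsolete_resolved: int = 0
    n_genes_emptied: int = 0


def close_annotation_set(
    ontology: Ontology,
    annotations: AnnotationSet,
    resolve_obsolete: bool = True,
    cache: ClosureCache | None = None,
    drop_roots: bool = False,
) -> tuple[AnnotationSet, ClosureSummary]:
    """Replace each gene's direct terms with the union of their closures.

    Each direct accession is resolved (primary / alt_id / obsolete
    replacement) and the closures of all resolution targets are unioned;
    unresolvable accessions are dropped from the gene and counted.  Genes
    left with nothing are retained with an empty term set.  Within a
    gene, closed accessions are ordered by numeric key.

    ``drop_roots`` removes parentless (namespace root) terms from the
    closed sets; off by default since root columns are trivially dropped
    downstream.
    """
    if cache is None:
        cache = ClosureCache()
    summary = ClosureSummary(n_genes=len(annotations.records))
    acc_of = {k: t.go_id for k, t in ontology.terms.items()}
    root_keys = {
        k for k, t in ontology.terms.items() if not t.is_obsolete and not t.parents
    }
    closed_records: list[tuple[str, tuple[str, ...]]] = []
    for gene_id, terms in annotations.records:
        closed: set[int] = set()
        for acc in terms:
            summary.n_direct_terms += 1
            res: Resolution = resolve_term(ontology, acc, resolve_obsolete=resolve_obsolete)
            if res.status == "unknown":
                summary.n_unresolved += 1
                continue
            if res.status in ("obsolete_replaced", "obsolete_consider"):
                summary.n_obsolete_resolved += 1
            for target in res.targets:
                closed.update(ancestors(ontology, target, cache))
        if drop_roots:
            closed -= root_keys
        if terms and not closed:
            summary.n_genes_emptied += 1
        closed_records.append(
            (gene_id, tuple(acc_of[k] for k in sorted(closed)))
        )
    return (
        AnnotationSet(records=closed_records, source_dialect=annotations.source_dialect),
        summary,
    )


def brute_force_reachable(
    edges: Iterable[tuple[int, int]], key: int
) -> set[int]:
    """Reachability by plain BFS over a raw (child, parent) edge list.

    Independent of the ontology structures above; used as the oracle in
    tests and by the fixture generator's ground-truth bookkeeping.
    """
    adj: dict[int, list[int]] = {}
    for child, parent in edges:
        adj.setdefault(child, []).append(parent)
    seen = {key}
    frontier = [key]
    while frontier:
        nxt = []
        for node in frontier:
            for parent in adj.get(node, ()):
                if parent not in seen:
                    seen.add(parent)
                    nxt.append(parent)
        frontier = nxt
    return seen
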