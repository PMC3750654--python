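"""Seeded synthetic ontologies and annotation files with exact ground truth.

Every other module is tested against data made here: valid OBO text for
a random DAG, plus generic-TSV and GAF renditions of the same gene
annotations.  All ground truth (per-term reachable sets, per-gene closed
sets, counts of injected malformed tokens and NOT lines, per-release
deltas) is recorded exactly by the generator itself — reachability is
computed by a plain BFS over the raw edge list, never by the closure
code under test.

Terms are created in topological order (each new term draws parents only
from earlier terms), so acyclicity holds by construction.  Annotation
sampling is leaf-biased (80% of draws from leaf terms by default),
mimicking the specificity profile of real GOA files so propagation
depth is actually exercised.
"""

from __future__ import annotations

import copy
import io
import random
from dataclasses import dataclass, field

from .closure import brute_force_reachable
from .errors import GomatrixError
from .obo_model import Ontology, OntologyTerm, serialize_obo

_GO_NAMESPACES = ("biological_process", "molecular_function", "cellular_component")


@dataclass
class FixtureTruth:
    """A synthetic ontology + annotations and everything known about them."""

    ontology: Ontology
    edges: list[tuple[int, int]] = field(default_factory=list)
    per_term_reachable: dict[int, set[int]] = field(default_factory=dict)
    #: gene -> tokens as written to the annotation files (valid ones only)
    per_gene_tokens: dict[str, list[str]] = field(default_factory=dict)
    #: gene -> closed set of numeric keys (resolution ON)
    per_gene_closed: dict[int | str, set[int]] = field(default_factory=dict)
    #: gene -> closed set when obsolete resolution is OFF
    per_gene_closed_noresolve: dict[str, set[int]] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    tsv_text: str = ""
    gaf_text: str = ""
    #: deltas recorded by evolve_release
    deltas: dict[str, int] = field(default_factory=dict)

    def obo_text(self) -> str:
        buf = io.StringIO()
        serialize_obo(self.ontology, buf)
        return buf.getvalue()


def _accession(prefix: str, key: int) -> str:
    return f"{prefix}:{key:07d}"


def generate_dag(
    n_terms: int,
    n_roots: int = 1,
    edge_density: float = 0.3,
    p_obsolete: float = 0.0,
    seed: int = 0,
    prefix: str = "GO",
    p_alt_id: float = 0.0,
    compute_reachable: bool = True,
) -> FixtureTruth:
    """Generate a random acyclic ontology.

    ``edge_density`` is the probability of each of up to two *extra*
    parents beyond the one every non-root term gets.  A ``p_obsolete``
    fraction of non-root slots become obsolete stanzas carrying either a
    ``replaced_by`` link or 1–2 ``consider`` targets to live terms.
    ``p_alt_id`` gives live terms a merged secondary accession drawn
    from an id range disjoint from the primaries.
    """
    if not (n_terms >= n_roots >= 1):
        raise GomatrixError("need n_terms >= n_roots >= 1")
    for name, v in [("edge_density", edge_density), ("p_obsolete", p_obsolete),
                    ("p_alt_id", p_alt_id)]:
        if not 0.0 <= v <= 1.0:
            raise GomatrixError(f"{name} must be a fraction in [0, 1]")
    rng = random.Random(seed)
    ontology = Ontology(format_version="1.2", source_date=f"seed:{seed}")
    edges: list[tuple[int, int]] = []
    live: list[int] = []
    obsolete: list[int] = []

    n_obsolete = round(p_obsolete * max(0, n_terms - n_roots))
    obsolete_slots: set[int] = set()
    if n_obsolete:
        obsolete_slots = set(rng.sample(range(n_roots + 1, n_terms + 1), n_obsolete))

    for key in range(1, n_terms + 1):
        is_root = key <= n_roots
        namespace = _GO_NAMESPACES[(key - 1) % 3] if is_root else ""
        term = OntologyTerm(
            numeric_key=key,
            go_id=_accession(prefix, key),
            name=f"synthetic term {key}",
            namespace=namespace,
            definition=f'"synthetic definition {key}" [auto:{seed}]',
        )
        ontology.terms[key] = term
        if is_root:
            live.append(key)
            continue
        if key in obsolete_slots:
            term.is_obsolete = True
            term.namespace = ontology.terms[rng.choice(live)].namespace
            obsolete.append(key)
            continue
        parents = [rng.choice(live)]
        for _ in range(2):
            if len(live) > 1 and rng.random() < edge_density:
                cand = rng.choice(live)
                if cand not in parents:
                    parents.append(cand)
        for p in parents:
            if rng.random() < 0.8:
                term.is_a_parents.append(p)
            else:
                term.part_of_parents.append(p)
            edges.append((key, p))
        term.namespace = ontology.terms[parents[0]].namespace
        live.append(key)

    # resolution hints for obsolete terms: replaced_by or consider
    for key in obsolete:
        term = ontology.terms[key]
        if rng.random() < 0.5:
            term.replaced_by = rng.choice(live)
        else:
            k = min(len(live), rng.choice((1, 2)))
            term.consider_targets = rng.sample(live, k)

    # alt_ids from a disjoint numeric range
    next_alt = n_terms + 1
    for key in live:
        if rng.random() < p_alt_id:
            alt = _accession(prefix, next_alt)
            ontology.terms[key].alt_ids.append(alt)
            ontology.alt_index[alt] = key
            next_alt += 1

    truth = FixtureTruth(ontology=ontology, edges=edges)
    if compute_reachable:
        # per-term ground truth by brute-force BFS (quadratic; skippable
        # for very large fixtures where only completion is exercised)
        for key in live:
            truth.per_term_reachable[key] = brute_force_reachable(edges, key)
    truth.counts.update(
        n_terms=n_terms, n_live=len(live), n_obsolete=len(obsolete),
        n_edges=len(edges),
    )
    return truth


def _resolve_with_truth(truth: FixtureTruth, token: str) -> list[int]:
    """Generator-side resolution of a token to live keys (independent of
    obo_model.resolve_term)."""
    ont = truth.ontology
    key = int(token.split(":")[1])
    if key in ont.terms and not ont.terms[key].is_obsolete:
        return [key]
    if token in ont.alt_index:
        return [ont.alt_index[token]]
    if key in ont.terms:
        term = ont.terms[key]
        if term.replaced_by is not None:
            return [term.replaced_by]
        return [c for c in term.consider_targets
                if not ont.terms[c].is_obsolete]
    return []


def generate_annotations(
    truth: FixtureTruth,
    n_genes: int,
    terms_per_gene_range: tuple[int, int] = (1, 4),
    p_malformed: float = 0.0,
    seed: int = 0,
    leaf_bias: float = 0.8,
    p_obsolete_token: float = 0.0,
    p_alt_token: float = 0.0,
    p_not_line: float = 0.0,
) -> FixtureTruth:
    """Annotate synthetic genes and emit TSV + GAF renditions in-place.

    Direct terms are drawn live and leaf-biased; with ``p_alt_token`` a
    term owning an alt_id is written under that secondary accession, and
    with ``p_obsolete_token`` an obsolete accession is written instead
    (its resolution targets enter the ground truth).  ``p_malformed``
    injects syntactically invalid tokens, and ``p_not_line`` injects
    GAF lines with a NOT qualifier; both are counted exactly.
    """
    rng = random.Random(seed)
    ont = truth.ontology
    live = sorted(k for k, t in ont.terms.items() if not t.is_obsolete)
    has_child = {p for _, p in truth.edges}
    leaves = sorted(k for k in live if k not in has_child) or live
    have_truth = bool(truth.per_term_reachable)
    obsolete_resolvable = sorted(
        k for k, t in ont.terms.items()
        if t.is_obsolete and _resolve_with_truth(truth, t.go_id)
    )
    alt_owners = sorted(
        (alt, k) for alt, k in ont.alt_index.items()
    )
    lo, hi = terms_per_gene_range
    if not (1 <= lo <= hi):
        raise GomatrixError("terms_per_gene_range must satisfy 1 <= lo <= hi")

    n_malformed = n_not = 0
    tsv_lines: list[str] = []
    gaf_lines: list[str] = ["!gaf-version: 2.0"]

    def gaf_line(gene: str, token: str, qualifier: str = "") -> str:
        cols = ["SYNTH", gene, gene, qualifier, token, "REF:0000001", "IEA",
                "", "P", f"{gene} product", "", "protein", "taxon:0000",
                "20130101", "SYNTH"]
        return "\t".join(cols)

    for i in range(1, n_genes + 1):
        gene = f"g{i:05d}"
        k = rng.randint(lo, hi)
        tokens: list[str] = []
        targets: set[int] = set()
        targets_noresolve: set[int] = set()
        for _ in range(k):
            roll = rng.random()
            if obsolete_resolvable and roll < p_obsolete_token:
                key = rng.choice(obsolete_resolvable)
                token = ont.terms[key].go_id
                tokens.append(token)
                targets.update(_resolve_with_truth(truth, token))
                # with resolution off this token is dropped
            elif alt_owners and roll < p_obsolete_token + p_alt_token:
                alt, owner = rng.choice(alt_owners)
                tokens.append(alt)
                targets.add(owner)
                targets_noresolve.add(owner)
            else:
                pool = leaves if rng.random() < leaf_bias else live
                key = rng.choice(pool)
                tokens.append(ont.terms[key].go_id)
                targets.add(key)
                targets_noresolve.add(key)
        # dedup preserving order, as the parsers do
        tokens = list(dict.fromkeys(tokens))
        cell_tokens = list(tokens)
        if rng.random() < p_malformed:
            cell_tokens.append(f"malformed_{i}")
            n_malformed += 1
        truth.per_gene_tokens[gene] = tokens
        if have_truth:
            truth.per_gene_closed[gene] = set().union(
                *(truth.per_term_reachable[t] for t in targets)
            ) if targets else set()
            truth.per_gene_closed_noresolve[gene] = set().union(
                *(truth.per_term_reachable[t] for t in targets_noresolve)
            ) if targets_noresolve else set()
        tsv_lines.append(f"{gene}\t{';'.join(cell_tokens)}")
        for token in cell_tokens:
            gaf_lines.append(gaf_line(gene, token))
        if live and rng.random() < p_not_line:
            gaf_lines.append(
                gaf_line(gene, ont.terms[rng.choice(live)].go_id, qualifier="NOT")
            )
            n_not += 1

    truth.counts.update(
        n_genes=n_genes,
        n_malformed_injected=n_malformed,
        n_not_injected=n_not,
        n_direct_tokens=sum(len(v) for v in truth.per_gene_tokens.values()),
    )
    truth.tsv_text = "\n".join(tsv_lines) + "\n"
    truth.gaf_text = "\n".join(gaf_lines) + "\n"
    return truth


def evolve_release(
    truth: FixtureTruth,
    n_obsolete: int = 0,
    n_rename: int = 0,
    n_add: int = 0,
    seed: int = 0,
) -> FixtureTruth:
    """Produce the next ontology release with recorded deltas.

    Obsoletes ``n_obsolete`` live leaf terms (each gets a replaced_by
    link to a surviving live term), renames ``n_rename`` other live
    terms (altering their definition fingerprint), and appends ``n_add``
    fresh terms parented to live terms.  The returned FixtureTruth's
    ``deltas`` are exact ground truth for the release diff.
    """
    rng = random.Random(seed)
    ont = copy.deepcopy(truth.ontology)
    ont.source_date = f"{truth.ontology.source_date}+evolved:{seed}"
    live = sorted(k for k, t in ont.terms.items() if not t.is_obsolete)
    has_child = {p for _, p in truth.edges}
    leaves = [k for k in live if k not in has_child and ont.terms[k].parents]
    if n_obsolete > len(leaves):
        raise GomatrixError("not enough live leaf terms to obsolete")

    to_obsolete = sorted(rng.sample(leaves, n_obsolete))
    survivors = [k for k in live if k not in set(to_obsolete)]
    for k in to_obsolete:
        t = ont.terms[k]
        t.is_obsolete = True
        t.is_a_parents = []
        t.part_of_parents = []
        t.replaced_by = rng.choice(survivors)

    renameable = [k for k in survivors]
    if n_rename > len(renameable):
        raise GomatrixError("not enough live terms to rename")
    to_rename = sorted(rng.sample(renameable, n_rename))
    for k in to_rename:
        ont.terms[k].name = f"renamed term {k} (r{seed})"

    prefix = next(iter(ont.terms.values())).go_id.split(":")[0] if ont.terms else "GO"
    next_key = max(ont.terms) + 1
    alt_keys = {int(a.split(":")[1]) for a in ont.alt_index}
    added: list[int] = []
    for _ in range(n_add):
        while next_key in alt_keys:
            next_key += 1
        parent = rng.choice(survivors)
        term = OntologyTerm(
            numeric_key=next_key,
            go_id=_accession(prefix, next_key),
            name=f"synthetic term {next_key}",
            namespace=ont.terms[parent].namespace,
            definition=f'"synthetic definition {next_key}" [auto:{seed}]',
            is_a_parents=[parent],
        )
        ont.terms[next_key] = term
        added.append(next_key)
        next_key += 1

    edges = [
        (k, p) for k, t in ont.terms.items() if not t.is_obsolete
        for p in t.parents
    ]
    new_truth = FixtureTruth(ontology=ont, edges=edges)
    for k, t in ont.terms.items():
        if not t.is_obsolete:
            new_truth.per_term_reachable[k] = brute_force_reachable(edges, k)
    new_truth.deltas = {
        "obsoleted": len(to_obsolete),
        "renamed": len(to_rename),
        "added": len(added),
    }
    new_truth.counts.update(
        n_terms=len(ont.terms),
        n_live=len(new_truth.per_term_reachable),
        n_edges=len(edges),
    )
    return new_truth
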