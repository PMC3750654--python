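# Methods

## Model and procedure

`gomatrix` implements true-path propagation of gene annotations over an
ontology DAG. The ontology is an OBO 1.2 flat file parsed into a term
table keyed by the numeric part of each accession; the parent structure
is restricted to `is_a` and `relationship: part_of`, the two relations
for which annotation transitivity holds. Other relationship types
(`regulates`, `has_part`, …) are deliberately not treated as parent
edges: propagating over them would assert memberships the annotation
semantics do not support. `consider` and `replaced_by` are modelled as
*resolution hints* attached to obsolete stanzas, never as graph edges —
treating `consider` as an edge would create links out of dead terms.

Identifier resolution proceeds in a fixed order: primary id, alt-id
index, then (for obsolete primaries, if enabled) `replaced_by` followed
transitively up to depth 5, else all `consider` targets, each themselves
resolved to live terms. The depth cap guards against malformed
replacement cycles; resolution never returns an obsolete target. An
alt_id owned by an obsolete primary continues down the obsolete path and
reports the obsolete status, so the no-obsolete-target guarantee is
unconditional.

The closure of a term is the term itself plus all is_a/part_of
ancestors. Including the term itself is forced by the matrix semantics:
direct annotations must appear as matrix memberships too. Closures are
computed iteratively (explicit stack, so ontology depth cannot overflow
the interpreter's recursion limit) and memoized in a term-keyed cache.
Each ontology edge is combined into a cached set exactly once, so the
total propagation work for an arbitrarily large annotation file is
O(|edges|), and the cache can never exceed the term count. The test
suite asserts both bounds with an edge-traversal counter.

Namespace roots are kept in closures and as matrix columns by default
(a `--drop-roots` flag removes parentless terms); part_of edges are
followed across namespaces without a firewall, treating the three GO
sub-ontologies as one structure.

## Inputs and outputs

Two annotation dialects are read: generic TAB-separated tables with
1-based user-specified gene and GO columns (multi-valued cells split on
`;` by default, `,` and `|` via flag) and GAF 2.x, where lines with a
`NOT` qualifier are excluded and counted. Duplicate gene rows merge by
term-set union, keeping first-occurrence order; tokens not matching
`prefix:digits` are counted as malformed and dropped. Non-GO prefixes
(e.g. `PO:`) are accepted throughout — the numeric key is the digit part
regardless of prefix.

The matrix is serialized as sorted `row<TAB>col<TAB>1` triplets with
1-based indices plus separate row-/column-name registries (one name per
line, line number = index), matching what R's `Matrix::sparseMatrix` and
Matlab's `spconvert` consume directly; the value column is kept although
always 1. A dense 0/1 TSV and a MatrixMarket writer are provided as
alternatives. Genes whose terms all failed resolution keep their
(all-zero) row so dimensions are stable across resolution settings.
All writers are byte-deterministic, and the CLI writes to a temporary
directory renamed into place on success, so a failed run leaves no
partial output.

## Release diffing

Two releases are compared term-by-term on the numeric key. A class
counts as *altered* when live in both releases but its
(name, namespace, definition) fingerprint differs — the minimal
attribute set the parser itself extracts; parent-edge changes are
tallied separately (`edges_changed`) so topology edits do not inflate
the altered count. Classes obsolete in both releases are ignored. The
headline percentage is (added + altered) / live classes in the *newer*
release: the fraction of current classes an analysis pinned to the old
release would miss or misname. Two partition identities
(`unaltered + altered + obsoleted + removed = old live` and
`unaltered + altered + added = new live`) hold by construction and are
property-tested. The turnover table reports live-class totals per
release and the arithmetic mean of consecutive differences.

## Synthetic data generator

The generator produces valid OBO text for random DAGs plus generic-TSV
and GAF renditions of the same annotations, with exact bookkeeping.
Terms are created in topological order — each new term draws its 1–3
parents from already-created live terms — so acyclicity holds by
construction; edge types are 80% `is_a` / 20% `part_of`. Obsolete
stanzas carry `replaced_by` or 1–2 `consider` links to live terms, and
alt_ids come from a numeric range disjoint from the primaries.
Annotation sampling is leaf-biased (80% of draws from leaf terms by
default), emulating the specificity profile of real GOA files so the
deep propagation path is actually exercised; malformed tokens and GAF
`NOT` lines are injected at configurable rates and counted exactly.
Ground-truth reachability is computed by a plain BFS over the raw edge
list, fully independent of the closure code it validates; per-term
truth is skippable (`compute_reachable=False`) for very large fixtures
where only completion and conservation are checked, since the
brute-force table is quadratic.

What the generator does *not* emulate: GO's power-law fan-in topology,
evidence codes, taxon structure, or realistic term-name vocabularies.
Passing tests therefore demonstrate structural correctness of parsing,
resolution, propagation and serialization — not robustness to the
idiosyncrasies of hand-curated real-world files beyond the OBO features
modelled. Release evolution obsoletes only leaf terms (each given a
`replaced_by` to a survivor), which keeps live-term reachability
well-defined without rewiring and matches the common curation case.

## Problem sizes and numerical choices

Default test fixtures use 150–500-term ontologies with 100–2,000 genes;
the oracle-equivalence check runs 200 random DAGs of 30–300 terms and
1,000 genes; the large-input smoke run uses a 20,000-term ontology with
100,000 genes (1–3 direct terms each), chosen as a realistic upper bound
for genome-scale annotation sets, and completes in well under a minute
within ~2 GiB. Everything is seed-deterministic: same seed, byte-
identical fixtures and outputs. Within genes, closed terms are ordered
by numeric key; triplets are sorted by (row, column); ties never arise
because memberships are sets.

## Known limitations

- OWL/RDF ontologies, GPAD/GPI annotation formats, and typedef semantics
  are out of scope.
- No evidence-code filtering (all associations accepted except `NOT`).
- No enrichment statistics, semantic similarity, or plotting — the
  matrix is deliberately the hand-off point to analysis environments.
- `consider` is consulted only for obsolete ids; if a file used it on
  live terms as a traversal link, those links would be ignored (a
  warning is logged when consider/replaced_by appear on live stanzas).
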