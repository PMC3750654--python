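"""Quantifying GO class turnover between ontology releases.

GO is edited daily: classes are added, redefined, merged and obsoleted.
Analyses pinned to an old release therefore miss or misname a measurable
fraction of current classes.  :func:`compare_ontologies` partitions the
classes of two releases into unaltered / altered / obsoleted / added /
removed and reports the percentage of the newer release's live classes
that an analysis using the older release would get wrong;
:func:`turnover_table` summarizes live-class growth across a dated
series of releases.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Sequence

from .errors import GomatrixError
from .obo_model import Ontology, OntologyTerm


def _fingerprint(term: OntologyTerm) -> tuple[str, str, str]:
    # minimal definition identity: name, namespace, definition text
    return (term.name, term.namespace, term.definition)


@dataclass
class DiffReport:
    """Set-algebra summary of two ontology releases.

    Two partition identities hold by construction::

        shared_unaltered + altered + obsoleted + removed == n_old_live
        shared_unaltered + altered + added == n_new_live
    """

    n_old_live: int
    n_new_live: int
    shared_unaltered: int
    altered: int
    obsoleted: int
    added: int
    removed: int
    edges_changed: int

    @property
    def altered_or_added(self) -> int:
        return self.added + self.altered

    @property
    def percent_altered(self) -> float:
        """Percent of the newer release's live classes that are new or
        redefined relative to the older release."""
        if self.n_new_live == 0:
            return 0.0
        return 100.0 * self.altered_or_added / self.n_new_live

    def summary_lines(self) -> list[str]:
        return [
            f"live classes (old)        {self.n_old_live}",
            f"live classes (new)        {self.n_new_live}",
            f"shared, unaltered         {self.shared_unaltered}",
            f"altered definition        {self.altered}",
            f"became obsolete           {self.obsoleted}",
            f"added                     {self.added}",
            f"removed                   {self.removed}",
            f"edge sets changed         {self.edges_changed}",
            f"added or altered          {self.altered_or_added}"
            f" ({self.percent_altered:.2f}% of current live classes)",
        ]


def compare_ontologies(old: Ontology, new: Ontology) -> DiffReport:
    """Diff two releases, keyed on the numeric part of the accession.

    A class is *altered* when live in both releases but its
    (name, namespace, definition) fingerprint differs; parent-edge
    changes are tallied separately as ``edges_changed`` and do not count
    as altered.  Classes obsolete in both releases are ignored.
    """
    old_live = {k for k, t in old.terms.items() if not t.is_obsolete}
    new_live = {k for k, t in new.terms.items() if not t.is_obsolete}

    shared_unaltered = altered = obsoleted = removed = edges_changed = 0
    for k in old_live:
        if k in new_live:
            if _fingerprint(old.terms[k]) == _fingerprint(new.terms[k]):
                shared_unaltered += 1
            else:
                altered += 1
            if (sorted(old.terms[k].is_a_parents), sorted(old.terms[k].part_of_parents)) != (
                sorted(new.terms[k].is_a_parents), sorted(new.terms[k].part_of_parents)
            ):
                edges_changed += 1
        elif k in new.terms:
            obsoleted += 1
        else:
            removed += 1
    added = len(new_live - old_live)

    return DiffReport(
        n_old_live=len(old_live),
        n_new_live=len(new_live),
        shared_unaltered=shared_unaltered,
        altered=altered,
        obsoleted=obsoleted,
        added=added,
        removed=removed,
        edges_changed=edges_changed,
    )


@dataclass
class TurnoverTable:
    """Live-class totals per release and the year-on-year deltas."""

    rows: list[tuple[str, int, int | None]]  # (label, total, change_from_previous)
    mean_change: float

    def write_tsv(self, stream: IO[str]) -> None:
        stream.write("release\ttotal_live_classes\tchange_from_previous\n")
        for label, total, change in self.rows:
            stream.write(f"{label}\t{total}\t{'' if change is None else change}\n")
        stream.write(f"# mean change per interval\t{self.mean_change:g}\n")


def turnover_table(
    ontologies: Sequence[Ontology], labels: Sequence[str] | None = None
) -> TurnoverTable:
    """Tabulate live-class totals over ≥2 date-ordered releases.

    Labels default to each ontology's header date.  The mean change is
    the arithmetic mean of consecutive differences — equivalently
    (last − first) / (n − 1).
    """
    if len(ontologies) < 2:
        raise GomatrixError("turnover needs at least two ontology releases")
    if labels is None:
        labels = [o.source_date or f"release_{i + 1}" for i, o in enumerate(ontologies)]
    if len(labels) != len(ontologies):
        raise GomatrixError("one label per ontology required")
    totals = [len(o.live_keys()) for o in ontologies]
    return turnover_from_totals(totals, labels)


def turnover_from_totals(
    totals: Sequence[int], labels: Sequence[str] | None = None
) -> TurnoverTable:
    """Turnover arithmetic from precomputed live-class totals."""
    if len(totals) < 2:
        raise GomatrixError("turnover needs at least two totals")
    if labels is None:
        labels = [str(i + 1) for i in range(len(totals))]
    changes = [b - a for a, b in zip(totals, totals[1:])]
    rows: list[tuple[str, int, int | None]] = [(labels[0], totals[0], None)]
    rows += [
        (labels[i + 1], totals[i + 1], changes[i]) for i in range(len(changes))
    ]
    return TurnoverTable(rows=rows, mean_change=sum(changes) / len(changes))
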