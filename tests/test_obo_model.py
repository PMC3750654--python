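import io
import textwrap

import pytest

from gomatrix.errors import CycleError, InvalidAccessionError, OboFormatError
from gomatrix.fixtures import generate_dag
from gomatrix.obo_model import (
    parse_obo,
    resolve_term,
    serialize_obo,
    split_accession,
)


def obo(text: str) -> str:
    return textwrap.dedent(text)


MINI = obo("""\
    format-version: 1.2

    [Term]
    id: GO:0000001
    name: R
    namespace: biological_process

    [Term]
    id: GO:0000002
    name: A
    namespace: biological_process
    is_a: GO:0000001

    [Term]
    id: GO:0000003
    name: B
    namespace: biological_process
    relationship: part_of GO:0000002
    """)


class TestParse:
    def test_minimal_dag(self):
        ont = parse_obo(io.StringIO(MINI))
        assert len(ont) == 3
        assert ont.terms[1].parents == []
        assert ont.terms[2].is_a_parents == [1]
        assert ont.terms[3].part_of_parents == [2]
        assert ont.format_version == "1.2"

    def test_is_a_comment_stripped(self):
        text = MINI.replace("is_a: GO:0000001", "is_a: GO:0000001 ! R")
        ont = parse_obo(io.StringIO(text))
        assert ont.terms[2].is_a_parents == [1]

    def test_windows_line_endings(self):
        ont = parse_obo(io.StringIO(MINI.replace("\n", "\r\n")))
        assert len(ont) == 3 and ont.terms[3].part_of_parents == [2]

    def test_header_date_optional(self):
        ont = parse_obo(io.StringIO(MINI))
        assert ont.source_date is None
        dated = "date: 01:02:2012 10:00\n" + MINI
        assert parse_obo(io.StringIO(dated)).source_date == "01:02:2012 10:00"

    def test_non_term_stanzas_skipped(self):
        text = MINI + obo("""\

            [Typedef]
            id: part_of
            name: part of
            """)
        assert len(parse_obo(io.StringIO(text))) == 3

    def test_non_go_prefix_accepted(self):
        text = MINI.replace("GO:", "PO:")
        ont = parse_obo(io.StringIO(text))
        assert ont.terms[2].go_id == "PO:0000002"
        assert ont.terms[2].is_a_parents == [1]

    def test_ignored_relationship_types_not_edges(self):
        text = MINI.replace(
            "relationship: part_of GO:0000002",
            "relationship: regulates GO:0000002",
        )
        ont = parse_obo(io.StringIO(text))
        assert ont.terms[3].parents == []

    def test_duplicate_id_rejected(self):
        text = MINI + "\n[Term]\nid: GO:0000002\nname: dup\n"
        with pytest.raises(OboFormatError, match="GO:0000002"):
            parse_obo(io.StringIO(text))

    def test_dangling_parent_rejected(self):
        text = MINI.replace("is_a: GO:0000001", "is_a: GO:0999999")
        with pytest.raises(OboFormatError, match="dangling"):
            parse_obo(io.StringIO(text))

    def test_cycle_rejected_with_witness(self):
        text = MINI.replace(
            "id: GO:0000001\nname: R\nnamespace: biological_process",
            "id: GO:0000001\nname: R\nnamespace: biological_process\nis_a: GO:0000003",
        )
        with pytest.raises(CycleError) as err:
            parse_obo(io.StringIO(text))
        cycle = err.value.cycle
        assert cycle[0] == cycle[-1] and len(set(cycle[:-1])) >= 2

    def test_stanza_without_id_reports_offset(self):
        text = MINI + "\n[Term]\nname: anonymous\n"
        with pytest.raises(OboFormatError, match="byte offset"):
            parse_obo(io.StringIO(text))


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_parse_serialize_identity(self, seed):
        """A parsed fixture ontology survives serialize→parse field-by-field."""
        truth = generate_dag(500, n_roots=3, edge_density=0.4,
                             p_obsolete=0.08, seed=seed, p_alt_id=0.1)
        first = parse_obo(io.StringIO(truth.obo_text()))
        buf = io.StringIO()
        serialize_obo(first, buf)
        second = parse_obo(io.StringIO(buf.getvalue()))
        assert first.terms == second.terms
        assert first.alt_index == second.alt_index
        assert first.source_date == second.source_date

    def test_matches_obonet_reference(self, tmp_path):
        """Independent OBO reader agrees on term count, obsoletes, is_a edges."""
        obonet = pytest.importorskip("obonet")
        truth = generate_dag(200, n_roots=2, edge_density=0.3,
                             p_obsolete=0.1, seed=9)
        path = tmp_path / "fixture.obo"
        path.write_text(truth.obo_text())
        ours = parse_obo(io.StringIO(truth.obo_text()))
        graph = obonet.read_obo(str(path))  # obonet drops obsolete stanzas
        live = [t for t in ours.terms.values() if not t.is_obsolete]
        assert len(graph) == len(live)
        ours_is_a = {
            (t.go_id, ours.terms[p].go_id) for t in live for p in t.is_a_parents
        }
        ref_is_a = {
            (u, v) for u, v, k in graph.edges(keys=True) if k == "is_a"
        }
        assert ours_is_a == ref_is_a


class TestResolve:
    def test_primary(self, resolution_ontology):
        res = resolve_term(resolution_ontology, "GO:0000002")
        assert (res.status, res.targets) == ("primary", (2,))

    def test_alt_id(self, resolution_ontology):
        res = resolve_term(resolution_ontology, "GO:0000099")
        assert (res.status, res.targets) == ("alt_id", (6,))

    def test_obsolete_replaced(self, resolution_ontology):
        res = resolve_term(resolution_ontology, "GO:0000004")
        assert (res.status, res.targets) == ("obsolete_replaced", (2,))

    def test_obsolete_consider_all_targets(self, resolution_ontology):
        res = resolve_term(resolution_ontology, "GO:0000005")
        assert (res.status, res.targets) == ("obsolete_consider", (2, 3))

    def test_unknown(self, resolution_ontology):
        res = resolve_term(resolution_ontology, "GO:0777777")
        assert (res.status, res.targets) == ("unknown", ())

    def test_resolution_switched_off(self, resolution_ontology):
        for acc in ("GO:0000004", "GO:0000005"):
            res = resolve_term(resolution_ontology, acc, resolve_obsolete=False)
            assert res.status == "unknown" and res.targets == ()
        # live lookups unaffected by the switch
        assert resolve_term(resolution_ontology, "GO:0000002",
                            resolve_obsolete=False).status == "primary"

    def test_invalid_accession_distinct_from_unknown(self, resolution_ontology):
        with pytest.raises(InvalidAccessionError):
            resolve_term(resolution_ontology, "not-an-accession")

    def test_replacement_chain_followed_to_live_term(self):
        # 1 live; 2..4 obsolete, each replaced by the previous
        stanzas = ["format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: live\n"]
        for k in range(2, 5):
            stanzas.append(
                f"[Term]\nid: GO:{k:07d}\nname: dead {k}\nis_obsolete: true\n"
                f"replaced_by: GO:{k - 1:07d}\n"
            )
        ont = parse_obo(io.StringIO("\n".join(stanzas)))
        res = resolve_term(ont, "GO:0000004")
        assert (res.status, res.targets) == ("obsolete_replaced", (1,))

    def test_replacement_chain_cap(self):
        # chain of 8 obsolete links exceeds the depth cap -> unknown
        stanzas = ["format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: live\n"]
        for k in range(2, 10):
            stanzas.append(
                f"[Term]\nid: GO:{k:07d}\nname: dead {k}\nis_obsolete: true\n"
                f"replaced_by: GO:{k - 1:07d}\n"
            )
        ont = parse_obo(io.StringIO("\n".join(stanzas)))
        assert resolve_term(ont, "GO:0000009").status == "unknown"

    def test_never_returns_obsolete_target(self, medium_ontology):
        for term in medium_ontology.terms.values():
            res = resolve_term(medium_ontology, term.go_id)
            for target in res.targets:
                assert not medium_ontology.terms[target].is_obsolete


def test_split_accession():
    assert split_accession("GO:0008150") == ("GO", 8150)
    assert split_accession("PO:0000123") == ("PO", 123)
    with pytest.raises(InvalidAccessionError):
        split_accession("GO0008150")
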