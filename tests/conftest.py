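import io
import textwrap

import pytest

from gomatrix.fixtures import generate_annotations, generate_dag
from gomatrix.obo_model import parse_obo

# Hand-written six-term ontology exercising every resolution path:
#   1 (root) <- 2 <- 3 (live chain)
#   4 obsolete, replaced_by 2
#   5 obsolete, consider 2 and 3
#   6 live, owns alt_id GO:0000099
RESOLUTION_OBO = textwrap.dedent("""\
    format-version: 1.2
    date: 01:01:2012 00:00

    [Term]
    id: GO:0000001
    name: root process
    namespace: biological_process

    [Term]
    id: GO:0000002
    name: mid process
    namespace: biological_process
    is_a: GO:0000001 ! root process

    [Term]
    id: GO:0000003
    name: leaf process
    namespace: biological_process
    relationship: part_of GO:0000002

    [Term]
    id: GO:0000004
    name: retired process
    namespace: biological_process
    is_obsolete: true
    replaced_by: GO:0000002

    [Term]
    id: GO:0000005
    name: split process
    namespace: biological_process
    is_obsolete: true
    consider: GO:0000002
    consider: GO:0000003

    [Term]
    id: GO:0000006
    name: merged process
    namespace: biological_process
    alt_id: GO:0000099
    is_a: GO:0000001
    """)


@pytest.fixture
def resolution_ontology():
    return parse_obo(io.StringIO(RESOLUTION_OBO))


@pytest.fixture(scope="session")
def medium_truth():
    """300-term DAG with obsoletes/alt_ids plus 1,000 annotated genes."""
    truth = generate_dag(300, n_roots=3, edge_density=0.3, p_obsolete=0.05,
                         seed=101, p_alt_id=0.1)
    return generate_annotations(
        truth, n_genes=1000, terms_per_gene_range=(1, 4), p_malformed=0.03,
        seed=102, p_obsolete_token=0.05, p_alt_token=0.05, p_not_line=0.02,
    )


@pytest.fixture(scope="session")
def medium_ontology(medium_truth):
    return parse_obo(io.StringIO(medium_truth.obo_text()))
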