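import pytest

from gofusion.ontology import parse_obo
from gofusion.synthetic import SyntheticConfig, generate_ontology, generate_proteome, split_dataset

CHAIN_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function
def: "the root process." [syn]

[Term]
id: GO:0000002
name: mid
namespace: molecular_function
def: "an intermediate process." [syn]
is_a: GO:0000001

[Term]
id: GO:0000003
name: leaf
namespace: molecular_function
def: "a specific process." [syn]
is_a: GO:0000002
"""

DIAMOND_OBO = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: molecular_function
def: "the root." [syn]

[Term]
id: GO:0000002
name: p1
namespace: molecular_function
def: "first parent." [syn]
is_a: GO:0000001

[Term]
id: GO:0000003
name: p2
namespace: molecular_function
def: "second parent." [syn]
relationship: part_of GO:0000001

[Term]
id: GO:0000004
name: leaf
namespace: molecular_function
def: "the leaf." [syn]
is_a: GO:0000002
relationship: part_of GO:0000003
"""


@pytest.fixture
def chain_graph():
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def diamond_graph():
    return parse_obo(DIAMOND_OBO)


@pytest.fixture(scope="session")
def study_task():
    """The planted benchmark at its default study conditions (seed 0)."""
    cfg = SyntheticConfig(seed=0)
    graph = generate_ontology(cfg)
    protein_ids, features, anns, planted = generate_proteome(graph, cfg)
    train, val, test = split_dataset(protein_ids, seed=cfg.seed)
    return {
        "config": cfg,
        "graph": graph,
        "protein_ids": protein_ids,
        "features": features,
        "annotations": anns,
        "planted": planted,
        "splits": {"train": train, "val": val, "test": test},
    }


@pytest.fixture(scope="session")
def ontology_50():
    """The 50-term seeded ontology used for label-encoder recovery checks."""
    return generate_ontology(SyntheticConfig(n_terms=50, seed=0))
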