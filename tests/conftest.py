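import io

import pytest

import vaxmap as vm
from vaxmap.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def abbrev():
    return vm.default_abbreviations()


@pytest.fixture(scope="session")
def stopwords():
    return vm.default_stopwords()


def make_graph(spec: dict, root: str = "R", property_labels=None) -> vm.OntologyGraph:
    """Build an OntologyGraph from a compact dict:
    id -> (label, [synonyms], [parents], [(prop, filler)])."""
    terms = {}
    for tid, entry in spec.items():
        label, synonyms, parents, restrictions = (list(entry) + [[], [], []])[:4]
        terms[tid] = vm.OntologyTerm(
            id=tid,
            label=label,
            synonyms=tuple(synonyms),
            parents=frozenset(parents),
            restrictions=tuple(restrictions),
        )
    return vm.OntologyGraph(root=root, terms=terms, property_labels=property_labels)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_fixture(FixtureSpec(seed=1, n_ineligible=3))


@pytest.fixture(scope="session")
def loaded_bundle(default_bundle):
    """The default bundle parsed into in-memory objects."""
    b = default_bundle
    sources = vm.read_source_table(io.StringIO(b.source_table))
    graph = vm.read_ontology(io.StringIO(b.ontology), root=b.vaccine_root)
    table = vm.AbbreviationTable.from_file(io.StringIO(b.abbreviations))
    gold = vm.read_gold(io.StringIO(b.gold))
    return b, sources, graph, table, gold


@pytest.fixture(scope="session")
def encoder():
    return vm.HashingTrigramEncoder(seed=0)
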