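"""Embedding-based candidate retrieval over a small generated ontology.

Generates a synthetic vocabulary/ontology pair, then retrieves mapping
candidates for one source term two ways: every ontology term scoring above
the 0.8 cosine threshold, and the unthresholded top-k ranking that the
hybrid refiners consume. Scores aggregate over each ontology term's label
and synonyms by the maximum.
"""

import io

import vaxmap as vm
from vaxmap.fixtures import FixtureSpec, generate_fixture

bundle = generate_fixture(FixtureSpec(seed=42, n_source_terms=10, n_ontology_terms=25))
sources = vm.read_source_table(io.StringIO(bundle.source_table))
graph = vm.read_ontology(io.StringIO(bundle.ontology), root=bundle.vaccine_root)
table = vm.AbbreviationTable.from_file(io.StringIO(bundle.abbreviations))

encoder = vm.HashingTrigramEncoder(seed=0)  # deterministic, no downloads
source = next(t for t in sources if t.eligible)
print(f"source term: {source.code} '{source.full_name}'")

def show(cand):
    # best_synonym_index 0 is the label; higher values name a synonym
    variant = graph[cand.object_id].variants[cand.best_synonym_index]
    via = "label" if cand.best_synonym_index == 0 else "synonym"
    print(f"  {cand.object_id}  {cand.score:.4f}  via {via} '{variant}'")


above = vm.embedding_candidates(source, graph, encoder, vm.MatchConfig(), table)
print(f"\n{len(above)} candidates above cosine 0.8:")
for c in above[:5]:
    show(c)

top = vm.top_k(source, graph, encoder, 5, table)
print("\ntop-5 ranking (no threshold):")
for c in top:
    show(c)
# The highest-scoring term is the planted counterpart of the source name;
# lower entries are lexical near-misses that refinement will discard.
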