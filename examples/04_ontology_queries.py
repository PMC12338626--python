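"""Existential-restriction (DL-style) queries over a mapped ontology.

Builds a small synthetic influenza branch in which four vaccines carry the
axiom `immunizes against pathogen some 'H1N1 subtype'` and three carry the
H3N2 analogue, then answers "which vaccines immunize against H1N1?" with
and without axiom inheritance down the subject hierarchy.
"""

import vaxmap as vm
from vaxmap.ontoquery import ClassExpressionQuery, query_restriction

terms = {
    "R": vm.OntologyTerm(id="R", label="vaccine"),
    "FLU": vm.OntologyTerm(id="FLU", label="influenza vaccine", parents=frozenset({"R"})),
    "PAT": vm.OntologyTerm(id="PAT", label="pathogen"),
    "IAV": vm.OntologyTerm(id="IAV", label="influenza A virus", parents=frozenset({"PAT"})),
    "H1N1": vm.OntologyTerm(id="H1N1", label="H1N1 subtype", parents=frozenset({"IAV"})),
    "H3N2": vm.OntologyTerm(id="H3N2", label="H3N2 subtype", parents=frozenset({"IAV"})),
}
for i in range(1, 5):
    terms[f"V{i}"] = vm.OntologyTerm(
        id=f"V{i}", label=f"H1N1 influenza vaccine {i}", parents=frozenset({"FLU"}),
        restrictions=(("immunizes_against_pathogen", "H1N1"),),
    )
for i in range(5, 8):
    terms[f"V{i}"] = vm.OntologyTerm(
        id=f"V{i}", label=f"H3N2 influenza vaccine {i}", parents=frozenset({"FLU"}),
        restrictions=(("immunizes_against_pathogen", "H3N2"),),
    )
# one brand-name product under V1 inherits its axiom
terms["V1b"] = vm.OntologyTerm(id="V1b", label="H1N1 vaccine brand",
                               parents=frozenset({"V1"}))
graph = vm.OntologyGraph(root="R", terms=terms)

q = ClassExpressionQuery(property_id="immunizes_against_pathogen", filler_id="H1N1")
hits = query_restriction(graph, q)
print(f"'immunizes against pathogen' some 'H1N1 subtype' -> {len(hits)} classes")
for tid in sorted(hits):
    print(f"  {tid}\t{graph[tid].label}")
# Four directly asserted vaccines plus the brand that inherits the axiom.

q_direct = ClassExpressionQuery(
    property_id="immunizes_against_pathogen", filler_id="H1N1",
    include_subject_descendants=False,
)
print(f"direct assertions only -> {len(query_restriction(graph, q_direct))} classes")
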