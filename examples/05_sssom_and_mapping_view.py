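"""SSSOM export and the annotated Turtle mapping view.

Writes one exact mapping (source code 03 to the measles-mumps-rubella
ontology class) as SSSOM TSV, reads it back, and emits the Turtle view in
which the mapped class carries the source code, full name and short
description as annotation properties.
"""

import io

import vaxmap as vm

graph = vm.OntologyGraph(
    root="VO_0000001",
    terms={
        "VO_0000001": vm.OntologyTerm(id="VO_0000001", label="vaccine"),
        "VO_0000731": vm.OntologyTerm(
            id="VO_0000731", label="Measles-Mumps-Rubella vaccine",
            parents=frozenset({"VO_0000001"}),
        ),
    },
)
source = vm.SourceTerm(
    code="03",
    full_name="measles, mumps and rubella virus vaccine",
    short_description="MMR",
)
record = vm.MappingRecord(
    subject_id="cvx:03",
    subject_label=source.full_name,
    object_id="VO_0000731",
    object_label="Measles-Mumps-Rubella vaccine",
    similarity_score=1.0,
)

sssom = vm.write_sssom([record])
print(sssom)
back = vm.read_sssom(io.StringIO(sssom))
print(f"round-trip identical: {back == [record]}\n")

print(vm.write_mapping_view([record], [source], graph))
# The ontology class now carries 'CVX code' 03 plus the full name and the
# short description, and keeps its asserted parent — the annotation pattern
# that embeds a flat code list inside the ontology.
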