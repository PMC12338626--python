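"""File IO: source tables, ontology branch extraction, SSSOM round-trips,
the annotated Turtle mapping view, gold files."""

import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vaxmap as vm
from vaxmap.errors import FormatError, ValidationError
from vaxmap.fixtures import paper_fixtures

TTL_12_TERMS = """\
@prefix obo: <http://purl.obolibrary.org/obo/> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix oio: <http://www.geneontology.org/formats/oboInOwl#> .

obo:VO_0000001 a owl:Class ; rdfs:label "vaccine" .
obo:VO_0000011 a owl:Class ; rdfs:label "viral vaccine" ; rdfs:subClassOf obo:VO_0000001 .
obo:VO_0000012 a owl:Class ; rdfs:label "measles vaccine" ;
    oio:hasExactSynonym "anti-measles vaccine" ;
    oio:hasRelatedSynonym "measles virus vaccine" ;
    rdfs:subClassOf obo:VO_0000011 .
obo:VO_0000013 a owl:Class ; rdfs:label "bacterial vaccine" ; rdfs:subClassOf obo:VO_0000001 .
obo:VO_0000014 a owl:Class ; rdfs:label "cholera vaccine" ; rdfs:subClassOf obo:VO_0000013 .
obo:ADJ_0000001 a owl:Class ; rdfs:label "vaccine adjuvant" .
obo:ADJ_0000002 a owl:Class ; rdfs:label "oil emulsion adjuvant" ; rdfs:subClassOf obo:ADJ_0000001 .
obo:PATHO_0000001 a owl:Class ; rdfs:label "pathogen" .
obo:PATHO_0000002 a owl:Class ; rdfs:label "measles virus" ; rdfs:subClassOf obo:PATHO_0000001 .
obo:IAO_0000030 a owl:Class ; rdfs:label "information content entity" .
obo:REC_0000001 a owl:Class ; rdfs:label "historical vaccination record" ; rdfs:subClassOf obo:IAO_0000030 .
obo:OGMS_0000104 a owl:Class ; rdfs:label "diagnostic process" .
"""


class TestReadSourceTable:
    def test_packaged_nonvaccine_table(self):
        path = paper_fixtures()["table2_nonvaccine_codes"]
        terms = vm.read_source_table(str(path))
        assert len(terms) == 9
        by_code = {t.code: t for t in terms}
        # the four skin-test rows are caught by name patterns alone
        patterns_only = vm.read_source_table(str(path), excluded_codes=())
        tst = [t for t in patterns_only if "tuberculin skin test" in t.full_name]
        assert len(tst) == 4 and not any(t.eligible for t in tst)
        # the full default configuration excludes every non-vaccine code
        assert not any(t.eligible for t in terms)
        assert by_code["801"].extra["VO Code"] == "VO_0001320"

    def test_header_only_file_yields_empty_list(self):
        stream = io.StringIO("CVX Code\tCVX Short Description\tFull Vaccine Name\tStatus\n")
        assert vm.read_source_table(stream) == []

    def test_missing_required_column_named_in_error(self):
        stream = io.StringIO("CVX Code\tStatus\n1\tActive\n")
        with pytest.raises(FormatError, match="Full Vaccine Name"):
            vm.read_source_table(stream)

    def test_duplicate_code_named_in_error(self):
        stream = io.StringIO(
            "CVX Code\tCVX Short Description\tFull Vaccine Name\tStatus\n"
            "7\ta\talpha vaccine\tActive\n7\tb\tbeta vaccine\tActive\n"
        )
        with pytest.raises(ValidationError, match="'7'"):
            vm.read_source_table(stream)

    def test_dialect_override_and_order_preserved(self):
        stream = io.StringIO(
            "id\tname\tdesc\n20\tzeta vaccine\tz\n10\talpha vaccine\ta\n"
        )
        terms = vm.read_source_table(
            stream,
            dialect={"code": "id", "full_name": "name", "short_description": "desc"},
        )
        assert [t.code for t in terms] == ["20", "10"]

    def test_reading_twice_is_stable(self):
        path = paper_fixtures()["table2_nonvaccine_codes"]
        assert vm.read_source_table(str(path)) == vm.read_source_table(str(path))


class TestReadOntology:
    def test_branch_restriction_matches_brute_force_reachability(self):
        graph = vm.read_ontology(io.StringIO(TTL_12_TERMS), root="VO_0000001")
        # brute-force closure over the asserted edges written in the fixture
        edges = {
            "VO_0000011": "VO_0000001",
            "VO_0000012": "VO_0000011",
            "VO_0000013": "VO_0000001",
            "VO_0000014": "VO_0000013",
            "ADJ_0000002": "ADJ_0000001",
            "PATHO_0000002": "PATHO_0000001",
            "REC_0000001": "IAO_0000030",
        }
        expected = {"VO_0000001"}
        changed = True
        while changed:
            changed = False
            for child, parent in edges.items():
                if parent in expected and child not in expected:
                    expected.add(child)
                    changed = True
        assert set(graph.terms) == expected
        assert len(graph) == 5

    def test_root_with_no_subclasses(self):
        graph = vm.read_ontology(io.StringIO(TTL_12_TERMS), root="OGMS_0000104")
        assert len(graph) == 1

    def test_synonyms_and_parents_captured(self):
        graph = vm.read_ontology(io.StringIO(TTL_12_TERMS), root="VO_0000001")
        term = graph["VO_0000012"]
        assert len(term.synonyms) == 2
        assert term.parents == {"VO_0000011"}

    def test_absent_root_rejected(self):
        with pytest.raises(ValidationError, match="VO_9999999"):
            vm.read_ontology(io.StringIO(TTL_12_TERMS), root="VO_9999999")

    def test_unparseable_document_is_a_format_error(self):
        with pytest.raises(FormatError):
            vm.read_ontology(io.StringIO("@prefix broken"), root="VO_0000001")

    def test_cycle_in_asserted_hierarchy_rejected(self):
        ttl = (
            "@prefix obo: <http://purl.obolibrary.org/obo/> .\n"
            "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n"
            "obo:VO_0000001 rdfs:subClassOf obo:VO_0000002 .\n"
            "obo:VO_0000002 rdfs:subClassOf obo:VO_0000001 .\n"
        )
        with pytest.raises(ValidationError, match="cycle"):
            vm.read_ontology(io.StringIO(ttl), root="VO_0000001")


records_strategy = st.lists(
    st.builds(
        vm.MappingRecord,
        subject_id=st.from_regex(r"cvx:[0-9]{1,3}", fullmatch=True),
        subject_label=st.text(
            alphabet="abcdefghijklmnop ,()-", min_size=0, max_size=20
        ).map(str.strip),
        object_id=st.from_regex(r"VO_[0-9]{7}", fullmatch=True),
        object_label=st.text(alphabet="abcdefgh ", max_size=15).map(str.strip),
        similarity_score=st.one_of(
            st.none(),
            st.integers(0, 10000).map(lambda i: i / 10000),
        ),
    ),
    max_size=8,
)


class TestSssom:
    def test_single_record_row(self):
        rec = vm.MappingRecord(
            subject_id="cvx:03",
            subject_label="measles, mumps and rubella virus vaccine",
            object_id="VO_0000731",
            object_label="Measles-Mumps-Rubella vaccine",
            similarity_score=1.0,
        )
        text = vm.write_sssom([rec])
        data_rows = [
            line for line in text.splitlines()
            if line and not line.startswith("#") and not line.startswith("subject_id")
        ]
        assert len(data_rows) == 1
        assert "Measles-Mumps-Rubella vaccine" in data_rows[0]
        assert "skos:exactMatch" in data_rows[0]

    def test_empty_record_list_is_metadata_and_header_only(self):
        text = vm.write_sssom([])
        lines = text.splitlines()
        assert lines[-1].startswith("subject_id\t")
        assert all(line.startswith("#") for line in lines[:-1])

    @settings(max_examples=100, deadline=None)
    @given(records_strategy)
    def test_write_then_read_is_identity(self, records):
        text = vm.write_sssom(records)
        back = vm.read_sssom(io.StringIO(text))
        assert back == records

    def test_metadata_only_file_reads_empty(self):
        assert vm.read_sssom(io.StringIO("# curie_map:\n#   VO: x\n")) == []

    def test_empty_object_id_rejected(self):
        text = "subject_id\tpredicate_id\tobject_id\ncvx:1\tskos:exactMatch\t\n"
        with pytest.raises(ValidationError):
            vm.read_sssom(io.StringIO(text))

    def test_missing_required_column_rejected(self):
        with pytest.raises(FormatError, match="object_id"):
            vm.read_sssom(io.StringIO("subject_id\tpredicate_id\ncvx:1\tskos:exactMatch\n"))

    def test_generated_gold_count_round_trips(self, loaded_bundle):
        bundle, sources, graph, table, gold = loaded_bundle
        eligible = [t for t in sources if t.eligible]
        assert len(gold) == len(eligible)
        text = vm.write_gold(gold)
        assert vm.read_gold(io.StringIO(text)) == gold


class TestMappingView:
    def _inputs(self):
        graph = vm.read_ontology(io.StringIO(TTL_12_TERMS), root="VO_0000001")
        source = vm.SourceTerm(
            code="208",
            full_name=(
                "SARS-COV-2 (COVID-19) vaccine, mRNA, spike protein, LNP, "
                "preservative free, 30 mcg/0.3mL dose"
            ),
            short_description="COVID-19, mRNA, LNP-S,PF, 30 mcg/0.3mL dose",
        )
        record = vm.MappingRecord(subject_id="cvx:208", object_id="VO_0000012")
        return graph, [source], [record]

    def test_annotations_for_code_and_full_name_present(self):
        graph, sources, records = self._inputs()
        text = vm.write_mapping_view(records, sources, graph)
        assert '"208"' in text
        assert "SARS-COV-2 (COVID-19) vaccine, mRNA, spike protein, LNP" in text

    def test_empty_records_emit_only_declarations(self):
        graph, sources, _ = self._inputs()
        text = vm.write_mapping_view([], sources, graph)
        assert "VO_0000012" not in text

    def test_round_trip_annotated_class_count(self):
        import rdflib

        graph, sources, records = self._inputs()
        text = vm.write_mapping_view(records, sources, graph)
        parsed = rdflib.Graph()
        parsed.parse(data=text, format="turtle")
        code_prop = rdflib.URIRef("https://w3id.org/vaxmap/sourceCode")
        annotated = set(parsed.subjects(code_prop, None))
        assert len(annotated) == len(records)

    def test_unknown_object_rejected(self):
        graph, sources, _ = self._inputs()
        bad = [vm.MappingRecord(subject_id="cvx:208", object_id="VO_7777777")]
        with pytest.raises(ValidationError):
            vm.write_mapping_view(bad, sources, graph)
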