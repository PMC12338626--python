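"""Reading and writing the toolkit's file formats.

* flat source-vocabulary tables (tab-delimited, CDC CVX dialect by default),
* OWL/RDF ontologies restricted to a root branch (via rdflib),
* SSSOM mapping files (commented-YAML metadata block + TSV body),
* an annotated Turtle "mapping view" reproducing the ontology annotation
  pattern (source code / full name / short description on each mapped
  class),
* gold-standard mapping tables and evaluation reports.
"""

from __future__ import annotations

import csv
import io
import re
from typing import IO, Iterable, Sequence

import yaml
from rdflib import BNode, Graph as RdfGraph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .errors import FormatError, ValidationError
from .model import (
    EvalReport,
    GoldRecord,
    MappingRecord,
    OntologyGraph,
    OntologyTerm,
    SourceTerm,
)

__all__ = [
    "DEFAULT_DIALECT",
    "DEFAULT_EXCLUDED_CODES",
    "DEFAULT_EXCLUSION_PATTERNS",
    "DEFAULT_SYNONYM_PROPERTIES",
    "read_source_table",
    "read_ontology",
    "write_sssom",
    "read_sssom",
    "write_mapping_view",
    "read_gold",
    "write_gold",
    "write_eval_report",
    "curieize",
]

# ---------------------------------------------------------------- source table

#: Logical column -> physical header, CDC CVX distribution dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "code": "CVX Code",
    "full_name": "Full Vaccine Name",
    "short_description": "CVX Short Description",
    "status": "Status",
}

#: Codes of non-vaccination records excluded from mapping by default: the
#: nine non-vaccine codes (skin tests, bookkeeping entries, the adjuvant
#: record) plus the deprecated duplicate tetanus-immune-globulin code 180.
#: Configuration, not biology — override per vocabulary.
DEFAULT_EXCLUDED_CODES: frozenset[str] = frozenset(
    {"95", "96", "97", "98", "99", "131", "180", "801", "998", "999"}
)

#: Name patterns (case-insensitive regex, matched against full name and
#: short description) that also mark a row ineligible.
DEFAULT_EXCLUSION_PATTERNS: tuple[str, ...] = (
    r"tuberculin skin test",
    r"no vaccine administered",
    r"reserved - do not use",
    r"unknown vaccine",
    r"historical record",
)

_REQUIRED_LOGICAL = ("code", "full_name", "short_description")


def read_source_table(
    stream: IO[str] | str,
    dialect: dict[str, str] | None = None,
    excluded_codes: Iterable[str] = DEFAULT_EXCLUDED_CODES,
    exclusion_patterns: Sequence[str] = DEFAULT_EXCLUSION_PATTERNS,
    delimiter: str = "\t",
) -> list[SourceTerm]:
    """Read a delimited source-vocabulary table into SourceTerms.

    ``dialect`` maps logical columns (code, full_name, short_description,
    optionally status) to physical headers; entries override the CVX
    defaults. Rows whose code is in ``excluded_codes`` or whose name matches
    an exclusion pattern are marked ``eligible=False``. Row order is
    preserved. Duplicate codes are a hard error.
    """
    close = False
    if isinstance(stream, str):
        stream = open(stream, encoding="utf-8")
        close = True
    try:
        cols = dict(DEFAULT_DIALECT)
        cols.update(dialect or {})
        reader = csv.DictReader(
            (line for line in stream if not line.startswith("#")),
            delimiter=delimiter,
        )
        header = reader.fieldnames
        if header is None:
            raise FormatError("source table has no header row")
        for logical in _REQUIRED_LOGICAL:
            if cols[logical] not in header:
                raise FormatError(
                    f"source table is missing required column {cols[logical]!r} "
                    f"(logical: {logical})"
                )
        excluded = {str(c) for c in excluded_codes}
        patterns = [re.compile(p, re.IGNORECASE) for p in exclusion_patterns]
        known_physical = set(cols.values())
        terms: list[SourceTerm] = []
        seen: set[str] = set()
        for row in reader:
            code = (row.get(cols["code"]) or "").strip()
            full_name = (row.get(cols["full_name"]) or "").strip()
            short = (row.get(cols["short_description"]) or "").strip()
            status = (row.get(cols.get("status", "Status")) or "").strip()
            if code in seen:
                raise ValidationError(f"duplicate source code {code!r}")
            seen.add(code)
            searchable = f"{full_name}\n{short}"
            eligible = code not in excluded and not any(
                p.search(searchable) for p in patterns
            )
            extra = {
                k: (v or "")
                for k, v in row.items()
                if k is not None and k not in known_physical
            }
            terms.append(
                SourceTerm(
                    code=code,
                    full_name=full_name,
                    short_description=short,
                    status=status,
                    eligible=eligible,
                    extra=extra,
                )
            )
        return terms
    finally:
        if close:
            stream.close()


# ------------------------------------------------------------------- ontology

OBO = "http://purl.obolibrary.org/obo/"
OBOINOWL = "http://www.geneontology.org/formats/oboInOwl#"

#: Synonym annotation properties harvested by default (OBO convention):
#: exact, related, broad and narrow synonyms.
DEFAULT_SYNONYM_PROPERTIES: tuple[str, ...] = (
    OBOINOWL + "hasExactSynonym",
    OBOINOWL + "hasRelatedSynonym",
    OBOINOWL + "hasBroadSynonym",
    OBOINOWL + "hasNarrowSynonym",
)

_CURIE_LOCAL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*_[A-Za-z0-9.-]+$")


def _iri_to_id(iri: str) -> str:
    """Canonical term id: OBO-style local name (VO_0000001) for OBO PURLs,
    otherwise the full IRI."""
    if iri.startswith(OBO):
        return iri[len(OBO) :]
    return iri


def _id_to_iri(term_id: str) -> URIRef:
    if "://" in term_id:
        return URIRef(term_id)
    if _CURIE_LOCAL_RE.match(term_id):
        return URIRef(OBO + term_id)
    raise ValidationError(f"cannot resolve term id {term_id!r} to an IRI")


def read_ontology(
    source: IO[str] | str,
    root: str,
    synonym_properties: Sequence[str] = DEFAULT_SYNONYM_PROPERTIES,
    rdf_format: str | None = None,
) -> OntologyGraph:
    """Parse an OWL/RDF document and keep the branch under ``root``.

    The graph contains the root class and exactly the classes reachable from
    it through inverse ``rdfs:subClassOf`` edges, with labels, synonyms
    (under ``synonym_properties``), direct parents, and existential
    restrictions ``(property_id, filler_id)`` asserted as superclasses.
    """
    g = RdfGraph()
    try:
        if isinstance(source, str):
            g.parse(source, format=rdf_format)
        else:
            data = source.read()
            g.parse(data=data, format=rdf_format or "turtle")
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001 - rdflib raises many types
        raise FormatError(f"cannot parse ontology document: {exc}") from exc

    root_iri = _id_to_iri(root)
    mentioned = set(g.subjects()) | set(g.objects())
    if root_iri not in mentioned:
        raise ValidationError(f"root {root!r} not present in ontology document")

    # direct subclass edges between named classes, and restriction edges
    children: dict[URIRef, set[URIRef]] = {}
    parents: dict[URIRef, set[URIRef]] = {}
    restrictions: dict[URIRef, list[tuple[str, str]]] = {}
    for s, o in g.subject_objects(RDFS.subClassOf):
        if not isinstance(s, URIRef):
            continue
        if isinstance(o, URIRef):
            children.setdefault(o, set()).add(s)
            parents.setdefault(s, set()).add(o)
        elif isinstance(o, BNode) and (o, RDF.type, OWL.Restriction) in g:
            prop = g.value(o, OWL.onProperty)
            filler = g.value(o, OWL.someValuesFrom)
            if isinstance(prop, URIRef) and isinstance(filler, URIRef):
                restrictions.setdefault(s, []).append(
                    (_iri_to_id(str(prop)), _iri_to_id(str(filler)))
                )

    # BFS down from the root over inverse subclass edges
    keep: set[URIRef] = {root_iri}
    frontier = [root_iri]
    while frontier:
        node = frontier.pop()
        for child in children.get(node, ()):
            if child not in keep:
                keep.add(child)
                frontier.append(child)

    syn_props = [URIRef(p) for p in synonym_properties]
    terms: dict[str, OntologyTerm] = {}
    property_labels: dict[str, str] = {}
    for iri in sorted(keep):
        tid = _iri_to_id(str(iri))
        labels = sorted(str(v) for v in g.objects(iri, RDFS.label))
        label = labels[0] if labels else tid
        synonyms = []
        for p in syn_props:
            synonyms.extend(str(v) for v in g.objects(iri, p))
        term_parents = frozenset(
            _iri_to_id(str(p)) for p in parents.get(iri, ()) if p in keep
        )
        terms[tid] = OntologyTerm(
            id=tid,
            label=label,
            synonyms=tuple(sorted(set(synonyms))),
            parents=term_parents,
            restrictions=tuple(sorted(restrictions.get(iri, ()))),
        )
        for prop_id, _ in restrictions.get(iri, ()):
            prop_iri = _id_to_iri(prop_id)
            plabels = sorted(str(v) for v in g.objects(prop_iri, RDFS.label))
            if plabels:
                property_labels[prop_id] = plabels[0]

    return OntologyGraph(
        root=_iri_to_id(str(root_iri)), terms=terms, property_labels=property_labels
    )


# --------------------------------------------------------------------- SSSOM

#: Fixed SSSOM column order used by the writer.
SSSOM_COLUMNS = (
    "subject_id",
    "subject_label",
    "predicate_id",
    "object_id",
    "object_label",
    "mapping_justification",
    "mapping_tool",
    "similarity_score",
)

_SCORE_PRECISION = 4


def curieize(code: str, prefix: str = "cvx") -> str:
    """Turn a bare source code into a CURIE (``54`` -> ``cvx:54``)."""
    if not code:
        raise ValidationError("cannot CURIE-ize an empty code")
    return f"{prefix}:{code}"


def write_sssom(
    records: Sequence[MappingRecord],
    metadata: dict[str, object] | None = None,
    stream: IO[str] | None = None,
) -> str:
    """Serialize mapping records as an SSSOM TSV.

    A commented YAML metadata block is followed by the header row and one
    tab-delimited row per record; similarity scores are rendered with four
    decimal places. Returns the serialized text (and writes it to ``stream``
    if given).
    """
    meta: dict[str, object] = {
        "curie_map": {
            "VO": OBO + "VO_",
            "cvx": "https://www2a.cdc.gov/vaccines/iis/iisstandards/vaccines.asp?rpt=cvx#",
            "skos": "http://www.w3.org/2004/02/skos/core#",
            "semapv": "https://w3id.org/semapv/vocab/",
        },
        "mapping_set_id": "https://w3id.org/vaxmap/mappings",
        "license": "https://creativecommons.org/licenses/by/4.0/",
    }
    meta.update(metadata or {})
    buf = io.StringIO()
    for line in yaml.safe_dump(meta, sort_keys=True).splitlines():
        buf.write(f"# {line}\n")
    buf.write("\t".join(SSSOM_COLUMNS) + "\n")
    for rec in records:
        score = (
            ""
            if rec.similarity_score is None
            else f"{rec.similarity_score:.{_SCORE_PRECISION}f}"
        )
        row = (
            rec.subject_id,
            rec.subject_label,
            rec.predicate_id,
            rec.object_id,
            rec.object_label,
            rec.mapping_justification,
            rec.mapping_tool,
            score,
        )
        buf.write("\t".join(row) + "\n")
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_sssom(stream: IO[str] | str) -> list[MappingRecord]:
    """Parse an SSSOM TSV as produced by :func:`write_sssom` (inverse on its
    image; the commented metadata block is skipped)."""
    close = False
    if isinstance(stream, str):
        stream = open(stream, encoding="utf-8")
        close = True
    try:
        lines = [line for line in stream if not line.startswith("#")]
    finally:
        if close:
            stream.close()
    if not lines:
        return []
    reader = csv.DictReader(lines, delimiter="\t")
    header = set(reader.fieldnames or ())
    for required in ("subject_id", "predicate_id", "object_id"):
        if required not in header:
            raise FormatError(f"SSSOM file is missing required column {required!r}")
    records = []
    for row in reader:
        object_id = (row.get("object_id") or "").strip()
        if not object_id:
            raise ValidationError(
                f"SSSOM row with subject {row.get('subject_id')!r} has an "
                "empty object_id"
            )
        score_text = (row.get("similarity_score") or "").strip()
        records.append(
            MappingRecord(
                subject_id=(row.get("subject_id") or "").strip(),
                subject_label=row.get("subject_label") or "",
                predicate_id=(row.get("predicate_id") or "").strip(),
                object_id=object_id,
                object_label=row.get("object_label") or "",
                mapping_justification=row.get("mapping_justification") or "",
                mapping_tool=row.get("mapping_tool") or "",
                similarity_score=float(score_text) if score_text else None,
            )
        )
    return records


# -------------------------------------------------------------- mapping view

VAXMAP_NS = Namespace("https://w3id.org/vaxmap/")
_ANNOTATIONS = (
    ("sourceCode", "CVX code", "code"),
    ("sourceFullName", "CVX full name", "full_name"),
    ("sourceShortDescription", "CVX short description", "short_description"),
)


def write_mapping_view(
    records: Sequence[MappingRecord],
    source_terms: Sequence[SourceTerm],
    graph: OntologyGraph,
    stream: IO[str] | None = None,
) -> str:
    """Emit a Turtle document in which every mapped ontology class carries
    the source code, full name and short description as annotation
    properties, plus its asserted parents — the annotation pattern used to
    integrate a flat code list into the ontology."""
    by_code = {t.code: t for t in source_terms}
    out = RdfGraph()
    out.bind("obo", OBO)
    out.bind("vaxmap", VAXMAP_NS)
    out.bind("owl", OWL)
    for attr, label, _ in _ANNOTATIONS:
        prop = VAXMAP_NS[attr]
        out.add((prop, RDF.type, OWL.AnnotationProperty))
        out.add((prop, RDFS.label, Literal(label)))
    for rec in records:
        if rec.object_id not in graph:
            raise ValidationError(
                f"mapping record {rec.subject_id} -> {rec.object_id}: object "
                "is not in the ontology graph"
            )
        code = rec.subject_id.rsplit(":", 1)[-1]
        src = by_code.get(code)
        if src is None:
            raise ValidationError(
                f"mapping record {rec.subject_id}: no source term with code {code!r}"
            )
        term = graph[rec.object_id]
        iri = _id_to_iri(term.id)
        out.add((iri, RDF.type, OWL.Class))
        out.add((iri, RDFS.label, Literal(term.label)))
        for attr, _, field_name in _ANNOTATIONS:
            value = getattr(src, field_name)
            if value:
                out.add((iri, VAXMAP_NS[attr], Literal(value)))
        for parent in sorted(term.parents):
            out.add((iri, RDFS.subClassOf, _id_to_iri(parent)))
    text = out.serialize(format="turtle")
    if stream is not None:
        stream.write(text)
    return text


# ------------------------------------------------------- gold & eval reports

_GOLD_HEADER = ("source_code", "exact_id", "acceptable_broader")


def write_gold(records: Sequence[GoldRecord], stream: IO[str] | None = None) -> str:
    """Serialize gold records as TSV: code, exact id or NONE, and a
    semicolon-separated list of acceptable broader ids."""
    buf = io.StringIO()
    buf.write("\t".join(_GOLD_HEADER) + "\n")
    for rec in records:
        buf.write(
            "\t".join(
                (
                    rec.source_code,
                    rec.exact_id if rec.exact_id is not None else "NONE",
                    ";".join(sorted(rec.acceptable_broader)),
                )
            )
            + "\n"
        )
    text = buf.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_gold(stream: IO[str] | str) -> list[GoldRecord]:
    close = False
    if isinstance(stream, str):
        stream = open(stream, encoding="utf-8")
        close = True
    try:
        reader = csv.DictReader(
            (line for line in stream if not line.startswith("#")), delimiter="\t"
        )
        header = set(reader.fieldnames or ())
        for required in ("source_code", "exact_id"):
            if required not in header:
                raise FormatError(f"gold file is missing required column {required!r}")
        records = []
        for row in reader:
            exact = (row.get("exact_id") or "").strip()
            broader_text = (row.get("acceptable_broader") or "").strip()
            broader = frozenset(b for b in broader_text.split(";") if b)
            records.append(
                GoldRecord(
                    source_code=(row.get("source_code") or "").strip(),
                    exact_id=None if exact in ("", "NONE") else exact,
                    acceptable_broader=broader,
                )
            )
        return records
    finally:
        if close:
            stream.close()


def write_eval_report(
    report: EvalReport, approach: str = "", stream: IO[str] | None = None
) -> str:
    """Serialize an evaluation report as a TSV with predicted/valid counts
    by verdict and the accuracy to four decimal places."""
    header = (
        "method",
        "predicted_mapped",
        "predicted_missing",
        "predicted_total",
        "valid_mapped",
        "valid_missing",
        "valid_total",
        "accuracy",
    )
    row = (
        approach,
        str(report.predicted_mapped),
        str(report.predicted_missing),
        str(report.predicted_total),
        str(report.valid_mapped),
        str(report.valid_missing),
        str(report.valid_total),
        f"{report.accuracy:.4f}",
    )
    text = "\t".join(header) + "\n" + "\t".join(row) + "\n"
    if stream is not None:
        stream.write(text)
    return text
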