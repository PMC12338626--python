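"""Asserted-hierarchy closure and existential-restriction queries.

Supports the DL-query use case "find every vaccine that ``immunizes against
pathogen`` some ``H1N1 subtype``" over the asserted subclass hierarchy: no
OWL reasoning beyond transitive closure of ``rdfs:subClassOf`` and downward
inheritance of restriction axioms (a subclass of a vaccine that immunizes
against a pathogen also immunizes against it).
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError
from .model import OntologyGraph

__all__ = ["ClassExpressionQuery", "ancestors", "descendants", "query_restriction"]


@dataclass(frozen=True)
class ClassExpressionQuery:
    """An existential class expression ``property some filler``.

    ``include_filler_descendants`` also accepts fillers below the given one
    in the filler hierarchy (a vaccine against an H1N1 strain is a vaccine
    against the H1N1 subtype); ``include_subject_descendants`` propagates a
    matched class's axiom to its own subclasses.
    """

    property_id: str
    filler_id: str
    include_filler_descendants: bool = True
    include_subject_descendants: bool = True

    def __post_init__(self) -> None:
        if not self.property_id or not self.filler_id:
            raise ValidationError("query needs non-empty property and filler ids")


def ancestors(graph: OntologyGraph, term_id: str) -> set[str]:
    """All ids reachable from ``term_id`` via asserted parent edges,
    excluding the term itself."""
    if term_id not in graph:
        raise ValidationError(f"unknown term {term_id!r}")
    seen: set[str] = set()
    frontier = [term_id]
    while frontier:
        node = frontier.pop()
        for parent in graph[node].parents:
            if parent in graph.terms and parent not in seen:
                seen.add(parent)
                frontier.append(parent)
    return seen


def descendants(graph: OntologyGraph, term_id: str) -> set[str]:
    """Inverse closure: all ids that have ``term_id`` among their ancestors."""
    if term_id not in graph:
        raise ValidationError(f"unknown term {term_id!r}")
    children = graph.children_index()
    seen: set[str] = set()
    frontier = [term_id]
    while frontier:
        node = frontier.pop()
        for child in children.get(node, ()):
            if child not in seen:
                seen.add(child)
                frontier.append(child)
    return seen


def query_restriction(
    graph: OntologyGraph,
    query: ClassExpressionQuery,
    filler_graph: OntologyGraph | None = None,
) -> set[str]:
    """Ids of all graph terms satisfying ``property some filler``.

    A term satisfies the query if it directly carries a restriction
    ``(property, f)`` with ``f`` the filler (or, when enabled, any
    descendant of the filler in ``filler_graph`` — the auxiliary hierarchy
    the fillers live in, e.g. a pathogen taxonomy; defaults to ``graph``
    itself) — or, when subject descendants are enabled, if any of its
    ancestors does.
    """
    known_properties = set(graph.property_labels)
    known_fillers: set[str] = set()
    for term in graph:
        for prop, filler in term.restrictions:
            known_properties.add(prop)
            known_fillers.add(filler)

    if query.property_id not in known_properties:
        raise ValidationError(f"unknown restriction property {query.property_id!r}")

    hierarchy = filler_graph if filler_graph is not None else graph
    fillers = {query.filler_id}
    if query.filler_id in hierarchy:
        if query.include_filler_descendants:
            fillers |= descendants(hierarchy, query.filler_id)
    elif query.filler_id not in known_fillers:
        raise ValidationError(f"unknown filler {query.filler_id!r}")

    direct = {
        term.id
        for term in graph
        if any(p == query.property_id and f in fillers for p, f in term.restrictions)
    }
    result = set(direct)
    if query.include_subject_descendants:
        for tid in direct:
            result |= descendants(graph, tid)
    return result
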