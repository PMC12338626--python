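"""Core domain types shared across the toolkit.

The objects here mirror the artefacts of a vocabulary-to-ontology mapping
exercise: rows of a flat source code table (:class:`SourceTerm`), classes of
an ontology restricted to a root branch (:class:`OntologyTerm`,
:class:`OntologyGraph`), scored mapping candidates, SSSOM-style mapping
records, per-term suggestions with a MAPPED/UNMAPPABLE verdict, gold-standard
records, and the curator-style evaluation report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: Verdicts a mapping suggestion can carry.
MAPPED = "MAPPED"
UNMAPPABLE = "UNMAPPABLE"

#: Recognised candidate-scoring methods.
METHODS = ("embedding", "jaccard", "llm")

#: Recognised pipeline approaches.
APPROACHES = ("embedding", "jaccard_hybrid", "llm_hybrid")


@dataclass(frozen=True)
class SourceTerm:
    """One row of the source vocabulary (e.g. a CVX code list entry).

    ``eligible`` is False for non-vaccination records (skin tests,
    bookkeeping codes) that are excluded from mapping.
    """

    code: str
    full_name: str
    short_description: str = ""
    status: str = ""
    eligible: bool = True
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.code:
            raise ValidationError("SourceTerm.code must be non-empty")
        if not self.full_name:
            raise ValidationError(
                f"SourceTerm {self.code!r}: full_name must be non-empty"
            )


@dataclass(frozen=True)
class OntologyTerm:
    """An ontology class: id, label, synonyms, asserted direct parents and
    existential restrictions ``(property_id, filler_id)``."""

    id: str
    label: str
    synonyms: tuple[str, ...] = ()
    parents: frozenset[str] = frozenset()
    restrictions: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("OntologyTerm.id must be non-empty")
        if not self.label:
            raise ValidationError(f"OntologyTerm {self.id}: label must be non-empty")

    @property
    def variants(self) -> tuple[str, ...]:
        """Label followed by all synonyms — the lexical information of the
        term, in the fixed order scoring code indexes into."""
        return (self.label, *self.synonyms)


class OntologyGraph:
    """An ontology branch: the root class plus every class reachable from it
    by inverse subclass edges, indexed by id.

    The asserted hierarchy must be acyclic; a cycle raises at construction.
    """

    def __init__(
        self,
        root: str,
        terms: dict[str, OntologyTerm],
        property_labels: dict[str, str] | None = None,
    ) -> None:
        if root not in terms:
            raise ValidationError(f"root {root!r} not among graph terms")
        self.root = root
        self.terms = dict(terms)
        self.property_labels = dict(property_labels or {})
        self._check_acyclic()
        self._children: dict[str, set[str]] | None = None

    def _check_acyclic(self) -> None:
        # iterative DFS with colour marks over in-graph parent edges
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {tid: WHITE for tid in self.terms}
        for start in self.terms:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, int]] = [(start, 0)]
            colour[start] = GREY
            while stack:
                node, i = stack.pop()
                parents = [p for p in self.terms[node].parents if p in self.terms]
                if i < len(parents):
                    stack.append((node, i + 1))
                    nxt = parents[i]
                    if colour[nxt] == GREY:
                        raise ValidationError(
                            f"cycle in asserted subclass hierarchy at {nxt!r}"
                        )
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        stack.append((nxt, 0))
                else:
                    colour[node] = BLACK

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __getitem__(self, term_id: str) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise ValidationError(f"unknown ontology term {term_id!r}") from None

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def children_index(self) -> dict[str, set[str]]:
        """id -> set of direct subclass ids (within the graph), cached."""
        if self._children is None:
            idx: dict[str, set[str]] = {tid: set() for tid in self.terms}
            for term in self.terms.values():
                for p in term.parents:
                    if p in self.terms:
                        idx[p].add(term.id)
            self._children = idx
        return self._children


@dataclass(frozen=True)
class ScoredCandidate:
    """An ontology term proposed as a match, with the similarity score and
    the method that produced it. ``best_synonym_index`` records which lexical
    variant (0 = label, 1.. = synonyms) achieved the score."""

    object_id: str
    score: float
    method: str
    best_synonym_index: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"unknown scoring method {self.method!r}")
        if not (self.score == self.score and abs(self.score) != float("inf")):
            raise ValidationError("candidate score must be finite")
        if self.method == "embedding" and not -1.0 <= self.score <= 1.0 + 1e-12:
            raise ValidationError("embedding score must lie in [-1, 1]")
        if self.method == "jaccard" and not 0.0 <= self.score <= 1.0:
            raise ValidationError("jaccard score must lie in [0, 1]")


@dataclass(frozen=True)
class MatchConfig:
    """Knobs of the matching pipeline.

    ``threshold`` — embedding cosine cut-off for the pure embedding approach
    (strictly greater-than); ``k_initial``/``k_final`` — candidate list sizes
    before and after refinement; ``jaccard_threshold`` — minimum token-set
    overlap kept by the word-level refiner.
    """

    threshold: float = 0.8
    k_initial: int = 20
    k_final: int = 10
    jaccard_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValidationError("threshold must lie in [0, 1]")
        if not 0.0 <= self.jaccard_threshold <= 1.0:
            raise ValidationError("jaccard_threshold must lie in [0, 1]")
        if self.k_final > self.k_initial:
            raise ValidationError("k_final must not exceed k_initial")
        if self.k_initial < 1:
            raise ValidationError("k_initial must be positive")


@dataclass(frozen=True)
class MappingRecord:
    """One SSSOM mapping row: source code (as a CURIE) to ontology term."""

    subject_id: str
    object_id: str
    subject_label: str = ""
    object_label: str = ""
    predicate_id: str = "skos:exactMatch"
    mapping_justification: str = "semapv:LexicalMatching"
    similarity_score: float | None = None
    mapping_tool: str = "vaxmap"

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValidationError("MappingRecord.subject_id must be non-empty")
        if not self.object_id:
            raise ValidationError("MappingRecord.object_id must be non-empty")
        if self.similarity_score is not None and not (
            0.0 <= self.similarity_score <= 1.0
        ):
            raise ValidationError("similarity_score must lie in [0, 1]")


@dataclass(frozen=True)
class MappingSuggestion:
    """Per source term: either MAPPED with a non-empty ordered candidate
    list, or UNMAPPABLE (a new ontology concept is recommended)."""

    source_code: str
    verdict: str
    candidates: tuple[ScoredCandidate, ...]
    approach: str

    def __post_init__(self) -> None:
        if self.verdict not in (MAPPED, UNMAPPABLE):
            raise ValidationError(f"unknown verdict {self.verdict!r}")
        if self.approach not in APPROACHES:
            raise ValidationError(f"unknown approach {self.approach!r}")
        if (self.verdict == MAPPED) != bool(self.candidates):
            raise ValidationError(
                "verdict MAPPED requires non-empty candidates and vice versa"
            )


@dataclass(frozen=True)
class GoldRecord:
    """Gold standard for one source code.

    ``exact_id`` is the single correct one-to-one match, or None when the
    term is missing from the ontology (correct verdict: UNMAPPABLE).
    ``acceptable_broader`` lists ids (typically the exact term's immediate
    parents) that also count as accurate for an automatic mapper.
    """

    source_code: str
    exact_id: str | None
    acceptable_broader: frozenset[str] = frozenset()


@dataclass(frozen=True)
class EvalReport:
    """Curator-style validity report: predicted and valid counts split by
    verdict, plus overall accuracy = valid_total / predicted_total."""

    predicted_mapped: int
    predicted_missing: int
    valid_mapped: int
    valid_missing: int

    def __post_init__(self) -> None:
        for name in (
            "predicted_mapped",
            "predicted_missing",
            "valid_mapped",
            "valid_missing",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if self.valid_mapped > self.predicted_mapped:
            raise ValidationError("valid_mapped exceeds predicted_mapped")
        if self.valid_missing > self.predicted_missing:
            raise ValidationError("valid_missing exceeds predicted_missing")

    @property
    def predicted_total(self) -> int:
        return self.predicted_mapped + self.predicted_missing

    @property
    def valid_total(self) -> int:
        return self.valid_mapped + self.valid_missing

    @property
    def accuracy(self) -> float:
        if self.predicted_total == 0:
            return 0.0
        return self.valid_total / self.predicted_total
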