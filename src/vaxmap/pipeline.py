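"""Orchestration of the three mapping approaches and their evaluation.

For each eligible source term one of three approaches is run:

* ``embedding`` — every ontology term whose max-over-synonyms cosine
  similarity exceeds the threshold;
* ``jaccard_hybrid`` — top-k embedding retrieval refined by word-level
  (token-set Jaccard) similarity;
* ``llm_hybrid`` — top-k embedding retrieval refined by a language-model
  client.

An empty candidate list yields the verdict UNMAPPABLE: the term has no
counterpart in the ontology and a new concept should be added. Suggestions
are scored against a gold standard with curator-style validity rules
(a MAPPED suggestion is valid when its candidates contain the correct term
or an acceptable broader one, typically the immediate parent; UNMAPPABLE is
valid when the gold standard marks the term missing), and mapped terms can
be classified by ontology branch.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .candidates import EncoderAdapter, embedding_candidates, top_k
from .errors import UsageError, ValidationError
from .model import (
    APPROACHES,
    MAPPED,
    UNMAPPABLE,
    EvalReport,
    GoldRecord,
    MappingRecord,
    MappingSuggestion,
    MatchConfig,
    OntologyGraph,
    SourceTerm,
)
from .normalize import AbbreviationTable
from .ontoquery import ancestors
from .refine import LlmClient, MockLlmClient, PromptTemplate, jaccard_refine, llm_refine
from .vocab_io import curieize

__all__ = [
    "suggest",
    "run_all",
    "evaluate",
    "classify_by_branch",
    "suggestions_to_records",
]

logger = logging.getLogger(__name__)


def suggest(
    source: SourceTerm,
    graph: OntologyGraph,
    approach: str,
    encoder: EncoderAdapter,
    config: MatchConfig = MatchConfig(),
    client: LlmClient | None = None,
    template: PromptTemplate | None = None,
    table: AbbreviationTable | None = None,
    stopwords: frozenset[str] | None = None,
) -> MappingSuggestion:
    """Run one approach for one source term and wrap the result in a
    MAPPED/UNMAPPABLE suggestion."""
    if approach not in APPROACHES:
        raise UsageError(f"unknown approach {approach!r}; choose from {APPROACHES}")
    if not source.eligible:
        raise UsageError(
            f"source term {source.code!r} is ineligible for mapping "
            "(non-vaccination record)"
        )
    if approach == "embedding":
        cands = embedding_candidates(source, graph, encoder, config, table, stopwords)
    else:
        initial = top_k(source, graph, encoder, config.k_initial, table, stopwords)
        if approach == "jaccard_hybrid":
            cands = jaccard_refine(source, initial, graph, config, table, stopwords)
        else:
            cands = llm_refine(
                source, initial, graph, client or MockLlmClient(), template, config
            )
    return MappingSuggestion(
        source_code=source.code,
        verdict=MAPPED if cands else UNMAPPABLE,
        candidates=tuple(cands),
        approach=approach,
    )


def run_all(
    sources: Sequence[SourceTerm],
    graph: OntologyGraph,
    approach: str,
    encoder: EncoderAdapter,
    config: MatchConfig = MatchConfig(),
    client: LlmClient | None = None,
    template: PromptTemplate | None = None,
    table: AbbreviationTable | None = None,
    stopwords: frozenset[str] | None = None,
) -> list[MappingSuggestion]:
    """One suggestion per eligible source term, in input order; ineligible
    terms are skipped and logged."""
    suggestions = []
    skipped = 0
    for source in sources:
        if not source.eligible:
            skipped += 1
            logger.info("skipping ineligible source term %s (%s)", source.code,
                        source.full_name)
            continue
        suggestions.append(
            suggest(
                source, graph, approach, encoder, config, client, template,
                table, stopwords,
            )
        )
    if skipped:
        logger.info("%d ineligible source terms skipped", skipped)
    return suggestions


def evaluate(
    suggestions: Sequence[MappingSuggestion], gold: Sequence[GoldRecord]
) -> EvalReport:
    """Score suggestions against a gold standard with curator-style rules.

    MAPPED is valid iff the candidate ids intersect {exact_id} plus the
    acceptable broader ids; UNMAPPABLE is valid iff the gold standard marks
    the term missing (exact_id NONE). Accuracy = valid / predicted, over all
    suggestions.
    """
    by_code = {g.source_code: g for g in gold}
    pm = pmiss = vm = vmiss = 0
    for sug in suggestions:
        record = by_code.get(sug.source_code)
        if record is None:
            raise ValidationError(
                f"no gold record for source code {sug.source_code!r}"
            )
        if sug.verdict == MAPPED:
            pm += 1
            acceptable = set(record.acceptable_broader)
            if record.exact_id is not None:
                acceptable.add(record.exact_id)
            if acceptable & {c.object_id for c in sug.candidates}:
                vm += 1
        else:
            pmiss += 1
            if record.exact_id is None:
                vmiss += 1
    return EvalReport(
        predicted_mapped=pm,
        predicted_missing=pmiss,
        valid_mapped=vm,
        valid_missing=vmiss,
    )


def classify_by_branch(
    records: Sequence[MappingRecord],
    graph: OntologyGraph,
    branch_roots: Sequence[str],
) -> dict[str, int]:
    """Count mapped ontology terms per branch.

    Each record's object is assigned to the first branch root (in the given
    order) found among the object itself and its asserted ancestors; objects
    under no listed branch — or absent from the graph — count as "other".
    Counts sum to ``len(records)``.
    """
    for root in branch_roots:
        if root not in graph:
            raise ValidationError(f"branch root {root!r} is not in the graph")
    counts: dict[str, int] = {root: 0 for root in branch_roots}
    counts["other"] = 0
    for rec in records:
        if rec.object_id not in graph:
            counts["other"] += 1
            continue
        lineage = {rec.object_id} | ancestors(graph, rec.object_id)
        for root in branch_roots:
            if root in lineage:
                counts[root] += 1
                break
        else:
            counts["other"] += 1
    return counts


def suggestions_to_records(
    suggestions: Sequence[MappingSuggestion],
    sources: Sequence[SourceTerm],
    graph: OntologyGraph,
    prefix: str = "cvx",
    predicate_id: str = "skos:exactMatch",
    mapping_tool: str = "vaxmap",
) -> list[MappingRecord]:
    """SSSOM records for the best candidate of every MAPPED suggestion."""
    by_code = {t.code: t for t in sources}
    justification_by_method = {
        "embedding": "semapv:SemanticSimilarityThresholdMatching",
        "jaccard": "semapv:LexicalSimilarityThresholdMatching",
        "llm": "semapv:MappingReview",
    }
    records = []
    for sug in suggestions:
        if sug.verdict != MAPPED:
            continue
        best = sug.candidates[0]
        src = by_code.get(sug.source_code)
        if src is None:
            raise ValidationError(f"no source term for code {sug.source_code!r}")
        score = best.score
        if not 0.0 <= score <= 1.0:  # embedding cosine may be negative
            score = max(0.0, min(1.0, score))
        records.append(
            MappingRecord(
                subject_id=curieize(sug.source_code, prefix),
                subject_label=src.full_name,
                predicate_id=predicate_id,
                object_id=best.object_id,
                object_label=graph[best.object_id].label,
                mapping_justification=justification_by_method.get(
                    best.method, "semapv:LexicalMatching"
                ),
                similarity_score=score,
                mapping_tool=mapping_tool,
            )
        )
    return records
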