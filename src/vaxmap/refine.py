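"""Refinement of embedding-retrieved candidates.

Two refiners narrow the top-k embedding candidates to at most ``k_final``:

* word-level refinement — Jaccard similarity between token sets
  (|intersection| / |union|), aggregated over a candidate's label and
  synonyms by maximum, thresholded and re-ranked;
* LLM refinement — a prompt listing the candidates is sent to a language
  model client, and the ids it selects (in its preference order) are kept.

The LLM stage ships as adapters only: a :class:`MockLlmClient` that is
deterministic given the prompt (used throughout the test suite), and the
:class:`LlmClient` protocol any production client can implement.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import IO, Protocol, Sequence, runtime_checkable

from .errors import ValidationError
from .model import MatchConfig, OntologyGraph, ScoredCandidate, SourceTerm
from .normalize import AbbreviationTable, normalize_text, tokenize

__all__ = [
    "LlmClient",
    "MockLlmClient",
    "PromptTemplate",
    "default_prompt_template",
    "jaccard",
    "jaccard_refine",
    "build_llm_prompt",
    "parse_llm_response",
    "llm_refine",
]

logger = logging.getLogger(__name__)


def jaccard(a: frozenset[str], b: frozenset[str]) -> float:
    """|a ∩ b| / |a ∪ b| over token sets; 0.0 when both are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def jaccard_refine(
    source: SourceTerm,
    top: Sequence[ScoredCandidate],
    graph: OntologyGraph,
    config: MatchConfig = MatchConfig(),
    table: AbbreviationTable | None = None,
    stopwords: frozenset[str] | None = None,
) -> list[ScoredCandidate]:
    """Word-level refinement of an embedding candidate list.

    Each candidate is re-scored as the maximum Jaccard similarity between
    the source full name's token set and the token set of any of the
    candidate's lexical variants; candidates at or above
    ``config.jaccard_threshold`` are kept, sorted by score descending (ties
    by id) and truncated to ``config.k_final``. An empty result makes the
    source term unmappable.
    """
    if len(top) > config.k_initial:
        raise ValidationError(
            f"refine input has {len(top)} candidates, more than k_initial="
            f"{config.k_initial}"
        )
    src_tokens = tokenize(normalize_text(source.full_name, table), stopwords)
    rescored = []
    for cand in top:
        term = graph[cand.object_id]  # raises ValidationError if absent
        best, best_idx = -1.0, 0
        for i, variant in enumerate(term.variants):
            s = jaccard(src_tokens, tokenize(normalize_text(variant, table), stopwords))
            if s > best:
                best, best_idx = s, i
        if best >= config.jaccard_threshold:
            rescored.append(
                ScoredCandidate(
                    object_id=term.id,
                    score=best,
                    method="jaccard",
                    best_synonym_index=best_idx,
                )
            )
    rescored.sort(key=lambda c: (-c.score, c.object_id))
    return rescored[: config.k_final]


@dataclass(frozen=True)
class PromptTemplate:
    """Prompt text with ``{source_term}`` and ``{candidates}`` placeholders,
    each required exactly once."""

    template: str

    def __post_init__(self) -> None:
        for placeholder in ("{source_term}", "{candidates}"):
            n = self.template.count(placeholder)
            if n != 1:
                raise ValidationError(
                    f"prompt template must contain {placeholder} exactly once "
                    f"(found {n})"
                )

    @classmethod
    def from_file(cls, stream: IO[str] | str) -> "PromptTemplate":
        if isinstance(stream, str):
            with open(stream, encoding="utf-8") as fh:
                return cls(fh.read())
        return cls(stream.read())


def default_prompt_template() -> PromptTemplate:
    """The shipped task prompt (task intro, rules, one example, inputs)."""
    text = (
        resources.files("vaxmap")
        .joinpath("data", "prompt_template.txt")
        .read_text(encoding="utf-8")
    )
    return PromptTemplate(text)


def build_llm_prompt(
    source: SourceTerm,
    top: Sequence[ScoredCandidate],
    graph: OntologyGraph,
    template: PromptTemplate | None = None,
) -> str:
    """Instantiate the prompt with the source full name and a numbered
    candidate list (``i. id - label``). Every candidate id appears exactly
    once in the output."""
    if not top:
        raise ValidationError("build_llm_prompt requires a non-empty candidate list")
    if template is None:
        template = default_prompt_template()
    lines = [
        f"{i}. {cand.object_id} - {graph[cand.object_id].label}"
        for i, cand in enumerate(top, 1)
    ]
    return template.template.format(
        source_term=source.full_name, candidates="\n".join(lines)
    )


def parse_llm_response(
    text: str, allowed_ids: Sequence[str], k_final: int = 10
) -> list[str]:
    """Extract candidate ids from a free-text model response.

    Ids not in ``allowed_ids`` (hallucinations) are dropped; duplicates keep
    their first occurrence; the list is truncated to ``k_final``. Lenient by
    design: an unparseable response yields an empty list with a warning.
    """
    allowed = list(dict.fromkeys(allowed_ids))
    hits: list[tuple[int, str]] = []
    for cid in allowed:
        m = re.search(re.escape(cid) + r"(?![A-Za-z0-9_])", text)
        if m:
            hits.append((m.start(), cid))
    hits.sort()
    ids = [cid for _, cid in hits][:k_final]
    if not ids and text.strip() and "NONE" not in text.upper():
        logger.warning("LLM response contained no recognised candidate id: %r", text[:200])
    return ids


@runtime_checkable
class LlmClient(Protocol):
    """Contract for language-model clients: map a prompt to a response."""

    name: str

    def complete(self, prompt: str) -> str: ...


class MockLlmClient:
    """Deterministic stand-in client for tests and offline runs.

    Parses the numbered candidate list out of the prompt and answers
    according to ``strategy``:

    * ``"first_k"`` — the first ``k`` listed ids, in order;
    * ``"reverse"`` — the first ``k`` ids in reversed order;
    * ``"none"`` — declares no candidate suitable.
    """

    _CAND_RE = re.compile(r"^\s*\d+\.\s+(\S+)\s+-\s", re.MULTILINE)

    def __init__(self, strategy: str = "first_k", k: int = 10, seed: int = 0) -> None:
        if strategy not in ("first_k", "reverse", "none"):
            raise ValidationError(f"unknown mock strategy {strategy!r}")
        self.strategy = strategy
        self.k = k
        self.seed = seed
        self.name = f"mock-{strategy}"

    def complete(self, prompt: str) -> str:
        if self.strategy == "none":
            return "NONE"
        ids = self._CAND_RE.findall(prompt)
        picked = ids[: self.k]
        if self.strategy == "reverse":
            picked = picked[::-1]
        return ", ".join(picked) if picked else "NONE"


def llm_refine(
    source: SourceTerm,
    top: Sequence[ScoredCandidate],
    graph: OntologyGraph,
    client: LlmClient,
    template: PromptTemplate | None = None,
    config: MatchConfig = MatchConfig(),
) -> list[ScoredCandidate]:
    """LLM refinement of an embedding candidate list.

    Builds the prompt, calls the client, parses the selected ids and returns
    them in the model's preference order, carrying over each candidate's
    embedding-stage score. Client failures raise an error naming the term.
    """
    if not top:
        return []
    prompt = build_llm_prompt(source, top, graph, template)
    try:
        response = client.complete(prompt)
    except Exception as exc:  # noqa: BLE001 - adapter boundary
        raise ValidationError(
            f"LLM client {getattr(client, 'name', '?')} failed on source term "
            f"{source.code!r}: {exc}"
        ) from exc
    by_id = {c.object_id: c for c in top}
    chosen = parse_llm_response(response, list(by_id), config.k_final)
    return [
        ScoredCandidate(
            object_id=cid,
            score=by_id[cid].score,
            method="llm",
            best_synonym_index=by_id[cid].best_synonym_index,
        )
        for cid in chosen
    ]
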