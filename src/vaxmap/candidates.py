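"""Embedding-based candidate retrieval.

Each source term's preprocessed full name and each ontology term's
preprocessed label/synonyms are encoded into fixed-dimension vectors by an
:class:`EncoderAdapter`; candidate ontology terms are ranked by cosine
similarity, aggregating over a term's lexical variants by the maximum
("best synonym wins"). The pure embedding approach keeps every term scoring
strictly above a threshold (default 0.8); the hybrid approaches instead take
the top-k (default 20) for downstream refinement.

Encoders are adapters. The default :class:`HashingTrigramEncoder` is a
deterministic character-trigram hashing encoder (no model weights, no
downloads, bit-reproducible across processes); a production adapter wrapping
a pretrained biomedical sentence-transformer is provided for real use and is
imported lazily.
"""

from __future__ import annotations

import zlib
from typing import Protocol, runtime_checkable

import numpy as np

from .errors import ValidationError
from .model import MatchConfig, OntologyGraph, OntologyTerm, ScoredCandidate, SourceTerm
from .normalize import AbbreviationTable, prepare

__all__ = [
    "EncoderAdapter",
    "HashingTrigramEncoder",
    "StaticEncoder",
    "SentenceTransformerEncoder",
    "cosine",
    "pair_similarity",
    "embedding_candidates",
    "top_k",
]


@runtime_checkable
class EncoderAdapter(Protocol):
    """Contract for sentence encoders: deterministic within a session,
    ``encode`` returns a 1-D float vector of length ``dimension``."""

    name: str
    dimension: int

    def encode(self, text: str) -> np.ndarray: ...


class HashingTrigramEncoder:
    """Deterministic character-trigram hashing encoder.

    Trigrams of the space-padded input are hashed (CRC32, seed-mixed) into
    ``dimension`` signed buckets; the count vector is L2-normalized. Similar
    strings share trigrams and therefore direction — a crude but fully
    reproducible stand-in for a trained sentence encoder, sufficient for
    lexical candidate retrieval and for exercising every pipeline stage
    offline.
    """

    def __init__(self, dimension: int = 384, seed: int = 0) -> None:
        if dimension < 2:
            raise ValidationError("encoder dimension must be >= 2")
        self.dimension = dimension
        self.seed = seed
        self.name = f"hash-trigram-{dimension}-s{seed}"
        self._salt = f"{seed}:".encode()
        self._cache: dict[str, np.ndarray] = {}

    def _features(self, text: str) -> list[str]:
        padded = f" {text} "
        if len(padded) < 3:
            return [padded]
        return [padded[i : i + 3] for i in range(len(padded) - 2)]

    def encode(self, text: str) -> np.ndarray:
        cached = self._cache.get(text)
        if cached is not None:
            return cached
        vec = np.zeros(self.dimension, dtype=np.float64)
        for gram in self._features(text):
            h = zlib.crc32(self._salt + gram.encode("utf-8"))
            bucket = (h >> 1) % self.dimension
            sign = 1.0 if (h & 1) else -1.0
            vec[bucket] += sign
        norm = np.linalg.norm(vec)
        if norm == 0.0:  # all trigrams cancelled; fall back to a unit basis
            vec[0] = 1.0
        else:
            vec /= norm
        vec.setflags(write=False)
        self._cache[text] = vec
        return vec


class StaticEncoder:
    """Lookup-table encoder for tests and worked examples: maps known
    strings to pre-set vectors."""

    def __init__(self, mapping: dict[str, "np.ndarray | list[float]"], name: str = "static") -> None:
        if not mapping:
            raise ValidationError("StaticEncoder requires at least one entry")
        self._table = {k: np.asarray(v, dtype=np.float64) for k, v in mapping.items()}
        dims = {v.shape for v in self._table.values()}
        if len(dims) != 1 or len(next(iter(dims))) != 1:
            raise ValidationError("all StaticEncoder vectors must share one 1-D shape")
        self.dimension = int(next(iter(dims))[0])
        self.name = name

    def encode(self, text: str) -> np.ndarray:
        try:
            return self._table[text]
        except KeyError:
            raise ValidationError(f"StaticEncoder has no vector for {text!r}") from None


class SentenceTransformerEncoder:
    """Production adapter around a pretrained sentence-transformer model
    (e.g. a 384-dimensional MiniLM variant trained on PubMed). Imported
    lazily; requires the optional ``sentence-transformers`` dependency."""

    def __init__(self, model_name: str = "NeuML/pubmedbert-base-embeddings") -> None:
        from sentence_transformers import SentenceTransformer  # lazy, optional

        self._model = SentenceTransformer(model_name)
        self.name = model_name
        self.dimension = int(self._model.get_sentence_embedding_dimension())
        self._cache: dict[str, np.ndarray] = {}

    def encode(self, text: str) -> np.ndarray:
        cached = self._cache.get(text)
        if cached is None:
            cached = np.asarray(self._model.encode(text), dtype=np.float64)
            self._cache[text] = cached
        return cached


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity dot(u, v) / (|u| |v|), in [-1, 1].

    Raises on mismatched shapes or a zero vector.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape or u.ndim != 1:
        raise ValidationError(f"cosine: incompatible shapes {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValidationError("cosine is undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def _source_text(
    source: SourceTerm,
    table: AbbreviationTable | None,
    stopwords: frozenset[str] | None,
) -> str:
    # Only the full name is embedded; the short description is not.
    return prepare(source.full_name, table, stopwords)


def pair_similarity(
    source: SourceTerm,
    term: OntologyTerm,
    encoder: EncoderAdapter,
    table: AbbreviationTable | None = None,
    stopwords: frozenset[str] | None = None,
) -> ScoredCandidate:
    """Similarity between a source term and one ontology term.

    Each lexical variant of the ontology term (label and every synonym) is
    scored individually against the source full name; the best score
    represents the pair, and ``best_synonym_index`` records which variant
    achieved it.
    """
    if not term.variants:
        raise ValidationError(f"{term.id}: term has no lexical variants")
    src_vec = encoder.encode(_source_text(source, table, stopwords))
    best_score = -np.inf
    best_idx = 0
    for i, variant in enumerate(term.variants):
        score = cosine(src_vec, encoder.encode(prepare(variant, table, stopwords)))
        if score > best_score:
            best_score, best_idx = score, i
    return ScoredCandidate(
        object_id=term.id,
        score=float(best_score),
        method="embedding",
        best_synonym_index=best_idx,
    )


def _score_all(
    source: SourceTerm,
    graph: OntologyGraph,
    encoder: EncoderAdapter,
    table: AbbreviationTable | None,
    stopwords: frozenset[str] | None,
) -> list[ScoredCandidate]:
    """Every graph term scored, sorted by score descending then id."""
    scored = [
        pair_similarity(source, term, encoder, table, stopwords) for term in graph
    ]
    scored.sort(key=lambda c: (-c.score, c.object_id))
    return scored


def embedding_candidates(
    source: SourceTerm,
    graph: OntologyGraph,
    encoder: EncoderAdapter,
    config: MatchConfig = MatchConfig(),
    table: AbbreviationTable | None = None,
    stopwords: frozenset[str] | None = None,
) -> list[ScoredCandidate]:
    """All ontology terms scoring strictly above ``config.threshold``,
    best first (ties broken by id). May be empty — the term is then
    unmappable under the pure embedding approach."""
    return [
        c
        for c in _score_all(source, graph, encoder, table, stopwords)
        if c.score > config.threshold
    ]


def top_k(
    source: SourceTerm,
    graph: OntologyGraph,
    encoder: EncoderAdapter,
    k: int,
    table: AbbreviationTable | None = None,
    stopwords: frozenset[str] | None = None,
) -> list[ScoredCandidate]:
    """The k best-scoring ontology terms (fewer if the graph is smaller),
    with no threshold applied: the hybrid approaches refine this list."""
    if k < 1:
        raise ValidationError("top_k requires k >= 1")
    return _score_all(source, graph, encoder, table, stopwords)[:k]
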