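"""Lexical normalization of vaccine term names.

Free-text vaccine names ("DTaP/IPV/HepB vaccine", "adenovirus vaccine,
type 4, live, oral") are folded to lowercase ASCII, vaccine-related
abbreviations and trade names are expanded from a table, punctuation is
replaced by whitespace, and the result is tokenized into a *set* of tokens
with English stopwords and the word "vaccine" removed. Token sets feed the
word-level (Jaccard) similarity; the order-preserving cleaned string feeds
the sentence encoder.

Abbreviation matching is whole-token and case-insensitive, longest key
first, in a single left-to-right pass (replacement text is never rescanned),
so expansion cannot loop and — provided expansions contain no table key as a
whole token, which the shipped table guarantees — normalization is
idempotent.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from typing import IO, Iterable

from .errors import FormatError, ValidationError

__all__ = [
    "AbbreviationTable",
    "default_abbreviations",
    "default_stopwords",
    "normalize_text",
    "prepare",
    "preprocess_term",
    "tokenize",
]

#: Characters treated as token separators (replaced by spaces after
#: abbreviation expansion): everything that is not a letter, digit or space.
_PUNCT_RE = re.compile(r"[^a-z0-9 ]")
_WS_RE = re.compile(r"\s+")

#: The one domain word always removed from token sets.
VACCINE_TOKENS = frozenset({"vaccine", "vaccines"})


def _ascii_fold(text: str) -> str:
    """Decompose accented characters and drop anything non-ASCII."""
    return (
        unicodedata.normalize("NFKD", text).encode("ascii", "ignore").decode("ascii")
    )


@dataclass(frozen=True)
class AbbreviationTable:
    """Abbreviation / trade-name expansion table.

    ``entries`` maps a lowercase match key to its expansion. Keys must be
    unique after case folding and expansions non-empty.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        folded: dict[str, str] = {}
        for key, expansion in self.entries.items():
            k = key.casefold().strip()
            if not k:
                raise ValidationError("abbreviation key must be non-empty")
            if not expansion or not expansion.strip():
                raise ValidationError(f"abbreviation {key!r}: expansion is empty")
            if k in folded:
                raise ValidationError(f"duplicate abbreviation key {key!r}")
            folded[k] = expansion.strip().casefold()
        object.__setattr__(self, "entries", folded)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AbbreviationTable":
        return cls(dict(pairs))

    @classmethod
    def from_file(cls, stream: IO[str] | str) -> "AbbreviationTable":
        """Read a two-column delimited table (key<TAB>expansion).

        Lines starting with '#' and blank lines are ignored.
        """
        close = False
        if isinstance(stream, str):
            stream = open(stream, encoding="utf-8")
            close = True
        try:
            pairs = []
            for lineno, raw in enumerate(stream, 1):
                line = raw.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise FormatError(
                        f"abbreviation table line {lineno}: expected two "
                        f"tab-separated columns, got {line!r}"
                    )
                pairs.append((parts[0], parts[1]))
            return cls.from_pairs(pairs)
        finally:
            if close:
                stream.close()

    def pattern(self) -> re.Pattern[str] | None:
        """Compiled whole-token alternation over keys, longest first."""
        if not self.entries:
            return None
        keys = sorted(self.entries, key=len, reverse=True)
        alt = "|".join(re.escape(k) for k in keys)
        return re.compile(rf"(?<![a-z0-9])({alt})(?![a-z0-9])")


def _read_data_text(name: str) -> str:
    return resources.files("vaxmap").joinpath("data", name).read_text(encoding="utf-8")


def default_abbreviations() -> AbbreviationTable:
    """The shipped vaccine abbreviation / trade-name table."""
    import io

    return AbbreviationTable.from_file(io.StringIO(_read_data_text("abbreviations.tsv")))


def default_stopwords() -> frozenset[str]:
    """The shipped English stopword list."""
    words = []
    for line in _read_data_text("stopwords.txt").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            words.append(line)
    return frozenset(words)


def normalize_text(text: str, table: AbbreviationTable | None = None) -> str:
    """Normalize one string: lowercase, ASCII folding, abbreviation
    expansion, punctuation-to-space, whitespace collapse.

    Idempotent on its own output (with the shipped table).
    """
    t = _ascii_fold(text.casefold())
    if table is not None:
        pat = table.pattern()
        if pat is not None:
            t = pat.sub(lambda m: table.entries[m.group(1)], t)
    t = _PUNCT_RE.sub(" ", t)
    return _WS_RE.sub(" ", t).strip()


def tokenize(
    normalized: str, stopwords: frozenset[str] | None = None
) -> frozenset[str]:
    """Split a normalized string into its token set, dropping stopwords and
    the word 'vaccine'. Set semantics: duplicates collapse."""
    if stopwords is None:
        stopwords = default_stopwords()
    return frozenset(
        tok
        for tok in normalized.split()
        if tok and tok not in stopwords and tok not in VACCINE_TOKENS
    )


def prepare(
    text: str,
    table: AbbreviationTable | None = None,
    stopwords: frozenset[str] | None = None,
) -> str:
    """Order-preserving variant of the full preprocessing: normalized text
    with stopwords and 'vaccine' removed but word order kept.

    This is the string handed to the sentence encoder; its token set equals
    ``tokenize(normalize_text(text, table), stopwords)``.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    words = [
        tok
        for tok in normalize_text(text, table).split()
        if tok not in stopwords and tok not in VACCINE_TOKENS
    ]
    return " ".join(words)


def preprocess_term(
    labels: list[str],
    table: AbbreviationTable | None = None,
    stopwords: frozenset[str] | None = None,
) -> list[tuple[str, frozenset[str]]]:
    """Normalize and tokenize a term's label plus all its synonyms.

    Returns one ``(normalized_string, token_set)`` pair per input string,
    order preserved.
    """
    if not labels:
        raise ValidationError("preprocess_term requires at least one label")
    out = []
    for label in labels:
        norm = normalize_text(label, table)
        out.append((norm, tokenize(norm, stopwords)))
    return out
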