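# Methods

## Problem setting

`vaxmap` aligns a flat source vocabulary of vaccine codes (code, full name,
short description, status) with a vaccine ontology (classes with labels,
synonyms, an asserted subclass hierarchy, and existential axioms such as
`immunizes against pathogen some X`). For each source code the pipeline
either suggests a ranked shortlist of candidate ontology classes for a
curator to review, or declares the code unmappable, i.e. recommends adding
a new ontology concept. The intended mapping semantics are exact and
one-to-one: a code maps to the single class that means the same thing;
mapping "downhill" to a more specific class (e.g. a brand-name product of
the vaccine) is disallowed, while mapping to the immediate parent is
accepted as accurate when no exact class exists yet.

## Eligibility

Not every row of a vaccine code list denotes a vaccine: skin-test reagents,
"no vaccine administered", reserved codes, historical bookkeeping entries
and deprecated duplicates are excluded from mapping. Eligibility is pure
configuration: a code list (shipped default: the nine non-vaccine codes of
the CVX distribution plus the deprecated duplicate tetanus-immune-globulin
code 180, ten in total) and case-insensitive name patterns
("tuberculin skin test", "no vaccine administered", …). Both are
overridable per vocabulary. Duplicate codes are a hard error rather than
silently deduplicated; known duplicates belong in the exclusion
configuration.

## Normalization (all approaches)

1. casefold, then NFKD decomposition with non-ASCII characters dropped;
2. abbreviation/trade-name expansion: whole-token, case-insensitive,
   longest key first, one left-to-right pass (replacement text is never
   rescanned, so expansion cannot loop). Slash-separated segments count as
   tokens, which is what expands `DTaP/IPV/HepB`;
3. every non-alphanumeric character becomes a space (hyphen, slash, comma,
   parentheses, period all split tokens — required so that hyphenated
   ontology labels and comma-separated code-list names tokenize alike);
4. tokenization into a *set*, dropping a fixed English stopword list and
   the word "vaccine"/"vaccines".

Numeric tokens are kept ("type 4" must survive); dosage fragments such as
`0.3mL` split into `0` and `3ml` — crude but harmless for set overlap, and
configurable by swapping the abbreviation table or stopword list (both are
package data, not code). No stemming, lemmatization or spell correction is
performed. Normalization is idempotent provided no expansion contains a
table key as a whole token; the shipped table satisfies this and the
property is tested. The embedding input is the same cleaned string with
word order preserved (stopwords removed, order kept); the Jaccard input is
its token set.

The shipped stopword and abbreviation lists are deliberately small and
generic. Published descriptions of this preprocessing never enumerate the
exact lists, so ours are chosen to reproduce the known worked examples and
are otherwise plain configuration.

## Embedding-based retrieval

Encoders are adapters (`name`, `dimension`, `encode(text) -> vector`). The
default `HashingTrigramEncoder` hashes character trigrams of the padded
string into 384 signed buckets (CRC32 mixed with a seed) and L2-normalizes;
it is fully deterministic across processes, needs no model weights, and
gives high cosine similarity to near-identical wordings — which is exactly
the regime lexical candidate retrieval operates in. It is a real encoder in
its own right, not a placeholder: all scores and rankings it produces are
bit-reproducible, which the determinism tests rely on. A
sentence-transformer adapter (384-dimensional biomedical MiniLM-style
models) is provided for production use and imported lazily.

Scoring: cosine similarity between the encoded source full name and each
lexical variant (label + every synonym) of the ontology class, aggregated
by maximum; the argmax variant index is recorded. Only the full name is
embedded on the source side. Candidate selection is either *thresholded*
(strictly greater than 0.8; the strict inequality matches the stated rule)
or *top-k* (default k = 20) for the hybrid refiners. The top-k list is
deliberately unthresholded; applying the 0.8 cut before refinement is a
plausible alternative reading and can be emulated by filtering the list
before handing it to a refiner. Ties are broken by lexicographic id for
determinism.

## Refinement

**Word-level**: each of the top-20 candidates is re-scored by the maximum
Jaccard coefficient between the source token set and any variant's token
set (per-variant max mirrors the embedding stage); candidates with
`J >= jaccard_threshold` are kept, sorted (score desc, id asc) and truncated
to `k_final = 10`. The threshold default 0.5 — majority token overlap — is a
documented package choice: the approach it reproduces was published without
its cutoff. Both refiners only ever shrink their input (subset property)
and never return more than `k_final` candidates.

**LLM**: the candidate list is rendered into a prompt (shipped template
with `{source_term}` and `{candidates}` placeholders; task intro, the
more-general-or-synonymous selection rule, one example) and sent to a
client adapter. Response parsing is lenient: candidate ids are extracted in
order of first occurrence, hallucinated ids dropped, and the list truncated
to `k_final`; candidates keep their embedding scores and the model's
preference order. The packaged `MockLlmClient` is deterministic given the
prompt (strategies: first-k, reversed, none) so that the whole pipeline is
testable offline; no provider SDK is imported anywhere.

## Evaluation

A gold record per code carries the exact class id or NONE (term missing
from the ontology) plus a set of acceptable broader ids, defaulting to the
exact class's direct parents. A MAPPED suggestion is valid iff its
candidate ids intersect `{exact} ∪ broader`; UNMAPPABLE is valid iff the
gold id is NONE. The report keeps predicted/valid counts per verdict as
integers and derives `accuracy = valid_total / predicted_total`, rendered
to four decimals in the TSV output. Counting the immediate parent as valid
follows the accuracy convention for broader mappings; suppliers can empty
`acceptable_broader` to score strict-exact only.

## Ontology handling and queries

Ontologies are read with rdflib (RDF/XML or Turtle); the graph keeps
exactly the classes reachable from the configured root by inverse
`rdfs:subClassOf` edges, their labels, synonyms under the four oboInOwl
synonym properties (exact/related/broad/narrow — a configurable guess,
since "all synonyms" is underspecified), direct named parents, and
existential restrictions asserted as superclass `owl:Restriction` nodes.
OBO PURLs are canonicalized to local ids (`VO_0000001`). Cycles in the
asserted hierarchy are a load-time error.

Queries implement asserted-closure semantics only: `ancestors`/
`descendants` are transitive closures, and `property some filler` matches
classes that directly carry the restriction with the filler (or any
descendant of the filler in an auxiliary filler hierarchy, e.g. a pathogen
taxonomy) plus, optionally, their own subclasses (axiom inheritance
downward). Both descendant expansions can be switched off, covering the
direct-assertions-only reading of DL query results. Equivalence axioms,
property chains and negation are out of scope; full reasoning belongs to a
dedicated reasoner.

## Synthetic fixtures: what they emulate and what they do not

`generate_fixture` builds the study conditions for offline testing: a
source table, ontology, abbreviation table and gold standard whose mapping
structure is planted and therefore known. Default shape: 25 source terms
over a 40-class vaccine branch — 40% exact token-set matches (same tokens,
different order/punctuation/case), 20% synonym-only matches, 12%
abbreviation-only matches (synthetic initialisms with their expansions
placed in the abbreviation table), 20% unmappable terms drawn from a
disjoint immune-globulin-style vocabulary, and the remainder near-miss
distractors that share exactly one token with some ontology class (overlap
≤ 1/6, safely below the 0.5 refinement threshold). The ontology adds a
parallel adjuvant branch, a pathogen hierarchy, and n_axiom_terms classes
carrying `immunizes against pathogen` restrictions, each with one
brand-name subclass to exercise axiom inheritance. Generation is
deterministic to the byte for a fixed seed, and the generator asserts that
no distractor is token-set-identical to any source term.

Fixture names are drawn from a fixed vaccine-flavoured word list; they do
not mimic real label-length or token-frequency distributions, real synonym
noise, or the semantic (non-lexical) matches a trained encoder would find.
Passing the parameter-recovery suite therefore shows the machinery is
correct — planted structure in, planted structure out — not that any
particular accuracy will be reached on a real vocabulary against a real
ontology release.

Two small static tables of printed reference data ship as package data:
the nine non-vaccine source codes with their ontology mappings, and the 24
passive-vaccine (immune globulin/antitoxin) codes, including the
deprecated duplicate tetanus-immune-globulin code noted in its source.

## Numerical and design choices

* Cosine is clipped to [-1, 1] against rounding; zero vectors are a domain
  error (the hashing encoder never emits one).
* All rankings break score ties by id; evaluation is order-invariant.
* SSSOM scores are serialized with four decimals; the write/read round-trip
  is the identity on records whose scores are already 4-decimal quantized.
* Test problem sizes (40–80-class ontologies, up to 273-row tables, 100
  random fixtures in the oracle-equivalence suites) are chosen so the whole
  suite completes in seconds while still covering every planted-match type;
  they are the package's own study conditions, set once.
* The annotation properties of the Turtle mapping view live in the package
  namespace `https://w3id.org/vaxmap/` with human-readable labels
  ("CVX code", "CVX full name", "CVX short description"), since the
  reference ontology's own property IRIs for these annotations are not
  published in a citable form.

## Known limitations

* No OBO flat-file output, no ontology release engineering, no network
  fetching of ontologies, no SPARQL endpoint.
* Asserted-subclass reasoning only; an ontology relying on equivalence
  axioms for its hierarchy will appear flatter than it is.
* The hashing encoder captures lexical, not semantic, similarity; truly
  synonymous but lexically disjoint pairs need the production
  sentence-transformer adapter (and its scores will differ from any
  published encoder-specific numbers).
* LLM refinement quality is entirely client-dependent; the package only
  guarantees the contract (subset of input, ≤ k_final, order preserved).
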