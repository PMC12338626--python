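# vaxmap

Semi-automated mapping of flat vaccine code lists to a vaccine ontology.

Clinical vaccine vocabularies such as the CDC's CVX ("Vaccine Administered")
code set are flat: a code, a full name, a short description — no hierarchy,
no semantics. Reference ontologies such as the Vaccine Ontology (VO) provide
the missing structure: a subclass hierarchy, synonyms, and logical axioms
like *`immunizes against pathogen` some `H1N1 subtype`*. Aligning the two is
usually done by curators, term by term. `vaxmap` implements the
candidate-suggestion machinery that makes this alignment semi-automatic: for
each eligible source code it either proposes a ranked shortlist of ontology
classes, or declares the code **unmappable**, signalling that a new ontology
concept is needed. It is aimed at terminology curators and ontology
engineers working on vocabulary harmonization (CVX, and by extension other
drug/vaccine code lists).

## Method

All term names are first normalized: lowercase/ASCII folding, expansion of
vaccine abbreviations and trade names (`DTaP/IPV/HepB` →
*diphtheria tetanus acellular pertussis / inactivated poliovirus /
hepatitis b*), punctuation and English stopword removal, and removal of the
word *vaccine* itself. Ontology terms contribute their label **and every
synonym**; a source–ontology pair is scored by the best variant
(max-aggregation).

Three approaches are provided:

1. **Embedding similarity** — sentence-encoder vectors compared by cosine
   `cos(u, v) = u·v / (‖u‖‖v‖)`; every ontology class with similarity
   `> 0.8` is a candidate.
2. **Word-level (Jaccard) hybrid** — the embedding top-20 is re-scored by
   the token-set Jaccard coefficient `J(A, B) = |A ∩ B| / |A ∪ B|` and
   pruned to at most 10 candidates at threshold `J ≥ 0.5`.
3. **LLM hybrid** — the embedding top-20 is filtered by a language-model
   prompt asking for candidates that are synonymous or more general
   (adapter + deterministic mock included; no network use required).

An empty candidate list ⇒ verdict `UNMAPPABLE`. Against a gold standard,
a `MAPPED` suggestion is *valid* if its candidates contain the correct class
(or an acceptable broader one, typically the immediate parent — "downhill"
mappings to more specific classes such as brand-name products are never
accepted); an `UNMAPPABLE` verdict is valid if the gold standard marks the
term missing. The report gives `accuracy = valid / predicted`.

On top of the mapping pipeline the package reads OWL/RDF ontologies
restricted to a root branch (default `VO_0000001` *vaccine*), writes SSSOM
mapping files and an annotated Turtle "mapping view" (source code / full
name / short description as annotation properties on each mapped class),
classifies mapped terms by ontology branch, and answers DL-style existential
queries (`property some filler`) over the asserted hierarchy.

## Worked example

`examples/03_full_pipeline_and_evaluation.py` generates a synthetic 273-row
code table (10 non-vaccination records), a matching 80-class ontology with
planted exact/synonym/abbreviation matches, and a gold standard, then runs
the word-level hybrid:

```
273 source rows, 263 eligible for mapping; 84 ontology classes under 'vaccine'
suggestions: 65 mapped, 198 unmappable (new ontology concepts recommended)
method          predicted_mapped  predicted_missing  predicted_total  valid_mapped  valid_missing  valid_total  accuracy
jaccard_hybrid  65                198                263              65            198            263          1.0000
```

Every planted match is recovered and every planted gap is flagged, so all
263 suggestions are valid (accuracy 1.0000 on this synthetic input; real
vocabularies are messier). The other examples cover normalization and
Jaccard (`01`), candidate retrieval (`02`), ontology queries (`04`), and
SSSOM/Turtle export (`05`); each prints the numbers it computes and a short
note on what they mean.

The same pipeline is available from the shell:

```bash
vaxmap fixtures --seed 7 --out fx
vaxmap map --source fx/source_table.tsv --ontology fx/ontology.ttl \
           --abbrev fx/abbreviations.tsv --gold fx/gold.tsv --out-dir out
vaxmap query --ontology fx/ontology.ttl --property VAXREL_0000001 \
             --filler PATHO_0000001 --filler-root PATHO_0000001
```

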