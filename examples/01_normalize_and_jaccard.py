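"""Lexical preprocessing and word-level similarity of two vaccine names.

Normalizes a source-vocabulary vaccine name and an ontology label
(lowercasing, abbreviation expansion, punctuation and stopword removal,
dropping the word 'vaccine'), tokenizes both into sets, and computes their
Jaccard coefficient |intersection| / |union|.
"""

import vaxmap as vm

table = vm.default_abbreviations()
stopwords = vm.default_stopwords()

source_name = "adenovirus vaccine, type 4, live, oral"
onto_label = "Adenovirus Type 4 Vaccine Live Oral Product"

src = vm.tokenize(vm.normalize_text(source_name, table), stopwords)
obj = vm.tokenize(vm.normalize_text(onto_label, table), stopwords)

print(f"source tokens   : {sorted(src)}")
print(f"ontology tokens : {sorted(obj)}")
print(f"intersection={len(src & obj)}  union={len(src | obj)}")
print(f"jaccard = {vm.jaccard(src, obj):.4f}")
# 5 shared tokens out of 6 distinct ones: the two names are near-identical
# wordings of the same vaccine (0.8333 > the 0.5 refinement threshold).

# Abbreviation expansion surfaces tokens hidden inside initialisms:
print(vm.normalize_text("DTaP/IPV/HepB vaccine", table))
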