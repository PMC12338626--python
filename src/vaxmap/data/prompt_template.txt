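You are assisting with mapping vaccine codes from a flat clinical
vocabulary to classes of a vaccine ontology.

Task: given one source vaccine term and a numbered list of 20 candidate
ontology terms retrieved by embedding similarity, identify up to 10
candidates that are either synonymous with the source term or more
general than it. Never select a candidate that is more specific than
the source term (for example a brand-name product of the source
vaccine). If no candidate qualifies, answer "NONE".

Output format: a comma-separated list of the selected candidate
identifiers, best match first.

Example: for the source term "measles, mumps and rubella virus vaccine",
given the candidates "Measles-Mumps-Rubella vaccine" (the exact class)
and "M-M-R II" (a brand-name product of that vaccine), select only the
identifier of "Measles-Mumps-Rubella vaccine": the brand is more
specific than the source term and must not be selected.

Begin with the following input:
Source term: {source_term}
Candidates:
{candidates}
Answer:
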