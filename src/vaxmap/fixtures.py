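"""Synthetic fixture generation.

:func:`generate_fixture` builds a matched quadruple of inputs — source code
table, ontology (Turtle), abbreviation table, gold standard — with fully
controlled mapping structure, so that every pipeline stage can be exercised
and checked offline against known ground truth:

* a fraction of source terms has a token-set-identical ontology label
  ("exact" matches);
* a fraction matches only through an ontology synonym;
* a fraction matches only after abbreviation expansion (the generator
  synthesizes an initialism and its expansion into the abbreviation table);
* a fraction is unmappable: its vocabulary is disjoint from the ontology's;
* the remainder are near-miss distractor sources sharing at most one token
  with any ontology term (kept below any majority-overlap threshold by
  construction).

The ontology contains a vaccine root branch, a parallel adjuvant branch, a
pathogen filler hierarchy, and ``n_axiom_terms`` vaccine classes carrying an
``immunizes against pathogen`` existential restriction, each with one
brand-name subclass (to exercise axiom inheritance). Everything is
deterministic for a fixed seed, down to the serialized bytes.

:func:`paper_fixtures` returns the packaged static tables of printed
reference data (the non-vaccine code table and the passive-vaccine table).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import ValidationError

__all__ = ["FixtureSpec", "FixtureBundle", "generate_fixture", "paper_fixtures"]

# Ontology vocabulary: disease/pathogen stems and formulation modifiers.
PATHOGENS = [
    "measles", "mumps", "rubella", "adenovirus", "cholera", "typhoid",
    "rabies", "polio", "dengue", "zoster", "anthrax", "ebola", "rotavirus",
    "smallpox", "tetanus", "pertussis", "diphtheria", "plague", "malaria",
    "influenza", "hepatitis", "varicella", "papillomavirus", "meningococcus",
    "pneumococcus", "leptospira", "borrelia", "brucella", "hantavirus",
    "coronavirus",
]
MODIFIERS = [
    "live", "attenuated", "inactivated", "recombinant", "conjugate",
    "adjuvanted", "oral", "intranasal", "monovalent", "bivalent",
    "trivalent", "tetravalent", "pediatric", "adult", "booster", "subunit",
    "toxoid", "mrna", "vectored", "split", "intradermal", "lyophilized",
]
# Vocabulary reserved for unmappable source terms (immune-globulin style).
PASSIVE_POOL = [
    "globulin", "antitoxin", "serum", "antibody", "monoclonal", "immune",
    "plasma", "hyperimmune", "antivenin", "polyclonal", "intramuscular",
    "intravenous",
]
# Vocabulary reserved for near-miss distractor sources.
NEARMISS_POOL = [
    "experimental", "candidate", "prototype", "research", "trial", "phase",
    "pilot", "novel", "preclinical", "draft", "bench", "exploratory",
]

TOP_ROOT = "VO_1000000"
VACCINE_ROOT = "VO_0000001"
ADJUVANT_ROOT = "VO_1000002"
ADJUVANT_TERM = "VO_1000003"
PATHOGEN_ROOT = "PATHO_0000001"
AXIOM_PROPERTY = "VAXREL_0000001"

_INELIGIBLE_CODES = sorted(
    ["95", "96", "97", "98", "99", "131", "180", "801", "998", "999"], key=int
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic fixture.

    Fractions apply to ``n_source_terms`` with floor rounding
    (``count = floor(frac * n_source_terms)``); the remainder of the source
    terms become near-miss distractors. ``n_ontology_terms`` counts vaccine
    classes under the vaccine root (excluding the root, brand-name children
    of axiom holders, and the adjuvant/pathogen branches).
    ``n_ineligible`` extra non-vaccination rows (flagged by the default
    exclusion codes/patterns) are appended to the source table.
    """

    n_ontology_terms: int = 40
    n_source_terms: int = 25
    frac_exact: float = 0.4
    frac_synonym: float = 0.2
    frac_abbrev: float = 0.12
    frac_unmappable: float = 0.2
    n_axiom_terms: int = 3
    n_ineligible: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_exact,
            self.frac_synonym,
            self.frac_abbrev,
            self.frac_unmappable,
        )
        if any(f < 0 for f in fracs):
            raise ValidationError("fixture fractions must be non-negative")
        if sum(fracs) > 1.0 + 1e-9:
            raise ValidationError("fixture fractions must sum to at most 1")
        if self.n_ontology_terms < 1 or self.n_source_terms < 1:
            raise ValidationError("fixture counts must be positive")
        if self.n_axiom_terms < 0 or self.n_ineligible < 0:
            raise ValidationError("fixture counts must be non-negative")
        if self.n_axiom_terms > self.n_ontology_terms:
            raise ValidationError("n_axiom_terms exceeds n_ontology_terms")
        planted = self.n_exact + self.n_synonym + self.n_abbrev
        if planted > self.n_ontology_terms:
            raise ValidationError(
                f"infeasible spec: {planted} planted matches exceed "
                f"n_ontology_terms={self.n_ontology_terms}"
            )

    @property
    def n_exact(self) -> int:
        return int(self.frac_exact * self.n_source_terms)

    @property
    def n_synonym(self) -> int:
        return int(self.frac_synonym * self.n_source_terms)

    @property
    def n_abbrev(self) -> int:
        return int(self.frac_abbrev * self.n_source_terms)

    @property
    def n_unmappable(self) -> int:
        return int(self.frac_unmappable * self.n_source_terms)


@dataclass
class FixtureBundle:
    """The generated fixture files (as text) plus the construction manifest."""

    source_table: str
    ontology: str
    abbreviations: str
    gold: str
    #: code -> one of exact / synonym / abbrev / unmappable / near_miss
    categories: dict[str, str] = field(default_factory=dict)
    #: ids of the vaccine classes carrying the planted restriction axiom
    axiom_holders: list[str] = field(default_factory=list)
    #: ids of their brand-name subclasses (inherit the axiom downward)
    axiom_children: list[str] = field(default_factory=list)
    vaccine_root: str = VACCINE_ROOT
    top_root: str = TOP_ROOT
    adjuvant_root: str = ADJUVANT_ROOT
    pathogen_root: str = PATHOGEN_ROOT
    axiom_property: str = AXIOM_PROPERTY
    axiom_filler: str = ""

    def write_to(self, directory: str | Path) -> dict[str, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, text in (
            ("source_table.tsv", self.source_table),
            ("ontology.ttl", self.ontology),
            ("abbreviations.tsv", self.abbreviations),
            ("gold.tsv", self.gold),
        ):
            path = directory / name
            path.write_text(text, encoding="utf-8")
            paths[name] = path
        return paths


def _sample_tokenset(
    rng: random.Random, pool: list[str], k: int, used: set[frozenset]
) -> list[str]:
    for _ in range(5000):
        words = rng.sample(pool, k)
        toks = frozenset(words)
        if len(toks) == k and toks not in used:
            used.add(toks)
            return words
    raise ValidationError(
        "cannot generate enough distinct synthetic term names; reduce counts"
    )


def _ttl_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate one deterministic fixture bundle from a spec."""
    rng = random.Random(spec.seed)
    vocab_pool = PATHOGENS + MODIFIERS

    n_exact, n_syn, n_abbr = spec.n_exact, spec.n_synonym, spec.n_abbrev
    n_unmap = spec.n_unmappable
    n_near = spec.n_source_terms - n_exact - n_syn - n_abbr - n_unmap

    used_sets: set[frozenset] = set()
    onto_terms: list[dict] = []  # id, label, synonyms, parent, tokens
    source_rows: list[dict] = []  # code, full_name, short, category, exact_id
    abbrev_entries: list[tuple[str, str]] = []

    def next_onto_id() -> str:
        return f"VO_{2000001 + len(onto_terms):07d}"

    # --- planted exact matches: ontology label and source name share tokens
    for _ in range(n_exact):
        p, m1, m2 = _sample_tokenset(rng, vocab_pool, 3, used_sets)
        tid = next_onto_id()
        onto_terms.append(
            {
                "id": tid,
                "label": f"{p} {m1} {m2} vaccine",
                "synonyms": [],
                "tokens": frozenset((p, m1, m2)),
            }
        )
        source_rows.append(
            {
                "full_name": f"{p} vaccine, {m2}, {m1}",
                "short": f"{p} {m1}",
                "category": "exact",
                "exact_id": tid,
            }
        )

    # --- matches reachable only through a synonym
    for _ in range(n_syn):
        p, m1, m2 = _sample_tokenset(rng, vocab_pool, 3, used_sets)
        q, w1, w2 = _sample_tokenset(rng, vocab_pool, 3, used_sets)
        tid = next_onto_id()
        onto_terms.append(
            {
                "id": tid,
                "label": f"{q} {w1} {w2} vaccine",
                "synonyms": [f"{p} {m1} {m2} vaccine"],
                "tokens": frozenset((q, w1, w2)),
            }
        )
        source_rows.append(
            {
                "full_name": f"{p} vaccine, {m1}, {m2}",
                "short": f"{p} {m2}",
                "category": "synonym",
                "exact_id": tid,
            }
        )

    # --- matches reachable only after abbreviation expansion
    for i in range(n_abbr):
        p, m1, m2 = _sample_tokenset(rng, vocab_pool, 3, used_sets)
        key = f"{p[0]}{m1[0]}x{i}"  # synthetic initialism; never a vocab word
        expansion = f"{p} {m1}"
        abbrev_entries.append((key, expansion))
        tid = next_onto_id()
        onto_terms.append(
            {
                "id": tid,
                "label": f"{p} {m1} {m2} vaccine",
                "synonyms": [],
                "tokens": frozenset((p, m1, m2)),
            }
        )
        source_rows.append(
            {
                "full_name": f"{key.upper()} vaccine, {m2}",
                "short": f"{key.upper()} {m2}",
                "category": "abbrev",
                "exact_id": tid,
            }
        )

    # --- ontology distractors up to n_ontology_terms
    for _ in range(spec.n_ontology_terms - len(onto_terms)):
        p, m1, m2 = _sample_tokenset(rng, vocab_pool, 3, used_sets)
        onto_terms.append(
            {
                "id": next_onto_id(),
                "label": f"{p} {m1} {m2} vaccine",
                "synonyms": [],
                "tokens": frozenset((p, m1, m2)),
            }
        )

    # --- unmappable sources: vocabulary disjoint from the ontology's
    for _ in range(n_unmap):
        r1, r2, r3 = _sample_tokenset(rng, PASSIVE_POOL, 3, used_sets)
        source_rows.append(
            {
                "full_name": f"{r1} {r2}, {r3}",
                "short": f"{r1} {r3}",
                "category": "unmappable",
                "exact_id": None,
            }
        )

    # --- near-miss sources: exactly one token shared with some ontology term
    for _ in range(n_near):
        donor = rng.choice(onto_terms)
        shared = sorted(donor["tokens"])[rng.randrange(3)]
        w1, w2, w3 = _sample_tokenset(rng, NEARMISS_POOL, 3, used_sets)
        source_rows.append(
            {
                "full_name": f"{shared} vaccine, {w1}, {w2}, {w3}",
                "short": f"{shared} {w1}",
                "category": "near_miss",
                "exact_id": None,
            }
        )

    # generation-time invariant: no distractor-only ontology term token set
    # equals a source token set it was not planted for
    planted_for = {row["exact_id"] for row in source_rows if row["exact_id"]}
    source_sets = {
        frozenset(w for w in row["full_name"].replace(",", " ").split() if w != "vaccine")
        for row in source_rows
        if row["category"] in ("exact", "near_miss", "unmappable")
    }
    for term in onto_terms:
        if term["id"] not in planted_for and term["tokens"] in source_sets:
            raise ValidationError("distractor term collides with a source term")

    # --- axiom holders: first n_axiom_terms vaccine classes get a
    # restriction to their own pathogen class, plus one brand-name child
    pathogen_classes: list[dict] = []
    axiom_holders: list[str] = []
    axiom_children: list[dict] = []
    for i, term in enumerate(onto_terms[: spec.n_axiom_terms]):
        stem = sorted(term["tokens"])[0]
        pid = f"PATHO_{2 + i:07d}"
        pathogen_classes.append({"id": pid, "label": f"{stem} pathogen {i}"})
        term["restriction"] = (AXIOM_PROPERTY, pid)
        axiom_holders.append(term["id"])
        axiom_children.append(
            {
                "id": f"VO_{3000001 + i:07d}",
                "label": f"{stem} brandname {i}",
                "parent": term["id"],
            }
        )

    # --- assemble source table (shuffled) with codes and ineligible rows
    rng.shuffle(source_rows)
    for i, row in enumerate(source_rows):
        row["code"] = str(1001 + i)
    ineligible_rows = []
    for i in range(spec.n_ineligible):
        if i < len(_INELIGIBLE_CODES):
            code = _INELIGIBLE_CODES[i]
        else:
            code = str(9001 + i)
        ineligible_rows.append(
            {
                "code": code,
                "full_name": f"tuberculin skin test; synthetic record {code}",
                "short": f"TST {code}",
                "category": "ineligible",
                "exact_id": None,
            }
        )
    all_rows = source_rows + ineligible_rows
    rng.shuffle(all_rows)

    header = "CVX Code\tCVX Short Description\tFull Vaccine Name\tStatus\n"
    table_lines = [header]
    for row in all_rows:
        table_lines.append(
            f"{row['code']}\t{row['short']}\t{row['full_name']}\tActive\n"
        )
    source_table = "".join(table_lines)

    # --- gold standard (eligible rows only, table order)
    gold_lines = ["source_code\texact_id\tacceptable_broader\n"]
    categories: dict[str, str] = {}
    for row in all_rows:
        categories[row["code"]] = row["category"]
        if row["category"] == "ineligible":
            continue
        exact = row["exact_id"] if row["exact_id"] else "NONE"
        broader = VACCINE_ROOT if row["exact_id"] else ""
        gold_lines.append(f"{row['code']}\t{exact}\t{broader}\n")
    gold = "".join(gold_lines)

    # --- abbreviation table
    abbrev_lines = ["# synthetic abbreviation table (key<TAB>expansion)\n"]
    for key, expansion in abbrev_entries:
        abbrev_lines.append(f"{key}\t{expansion}\n")
    abbreviations = "".join(abbrev_lines)

    # --- ontology as Turtle
    obo = "http://purl.obolibrary.org/obo/"
    t = [
        f"@prefix obo: <{obo}> .\n",
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n",
        "@prefix oio: <http://www.geneontology.org/formats/oboInOwl#> .\n\n",
        f'obo:{AXIOM_PROPERTY} a owl:ObjectProperty ; rdfs:label "immunizes against pathogen" .\n\n',
        f'obo:{TOP_ROOT} a owl:Class ; rdfs:label "biological preparation" .\n',
        f'obo:{VACCINE_ROOT} a owl:Class ; rdfs:label "vaccine" ; rdfs:subClassOf obo:{TOP_ROOT} .\n',
        f'obo:{ADJUVANT_ROOT} a owl:Class ; rdfs:label "vaccine adjuvant" ; rdfs:subClassOf obo:{TOP_ROOT} .\n',
        f'obo:{ADJUVANT_TERM} a owl:Class ; rdfs:label "squalene oil emulsion adjuvant" ; rdfs:subClassOf obo:{ADJUVANT_ROOT} .\n',
        f'obo:{PATHOGEN_ROOT} a owl:Class ; rdfs:label "pathogen" .\n',
    ]
    for pc in pathogen_classes:
        t.append(
            f'obo:{pc["id"]} a owl:Class ; rdfs:label "{_ttl_escape(pc["label"])}" ; '
            f"rdfs:subClassOf obo:{PATHOGEN_ROOT} .\n"
        )
    t.append("\n")
    for term in onto_terms:
        parts = [
            f'obo:{term["id"]} a owl:Class ; rdfs:label "{_ttl_escape(term["label"])}"'
        ]
        for syn in term["synonyms"]:
            parts.append(f'oio:hasExactSynonym "{_ttl_escape(syn)}"')
        parts.append(f"rdfs:subClassOf obo:{VACCINE_ROOT}")
        if "restriction" in term:
            prop, filler = term["restriction"]
            parts.append(
                "rdfs:subClassOf [ a owl:Restriction ; "
                f"owl:onProperty obo:{prop} ; owl:someValuesFrom obo:{filler} ]"
            )
        t.append(" ; ".join(parts) + " .\n")
    for child in axiom_children:
        t.append(
            f'obo:{child["id"]} a owl:Class ; rdfs:label "{_ttl_escape(child["label"])}" ; '
            f"rdfs:subClassOf obo:{child['parent']} .\n"
        )
    ontology = "".join(t)

    return FixtureBundle(
        source_table=source_table,
        ontology=ontology,
        abbreviations=abbreviations,
        gold=gold,
        categories=categories,
        axiom_holders=axiom_holders,
        axiom_children=[c["id"] for c in axiom_children],
        axiom_filler=pathogen_classes[0]["id"] if pathogen_classes else "",
    )


def paper_fixtures() -> dict[str, Path]:
    """Paths to the packaged static reference tables.

    ``table2_nonvaccine_codes`` — the nine non-vaccine source codes with
    their ontology mappings; ``table5_passive_vaccines`` — the 24
    immune-globulin/antitoxin codes classified under 'passive vaccine'
    (including the deprecated duplicate tetanus-immune-globulin code).
    Both are readable with :func:`vaxmap.vocab_io.read_source_table`.
    """
    data = resources.files("vaxmap").joinpath("data")
    return {
        "table2_nonvaccine_codes": Path(str(data.joinpath("table2_nonvaccine_codes.tsv"))),
        "table5_passive_vaccines": Path(str(data.joinpath("table5_passive_vaccines.tsv"))),
    }
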