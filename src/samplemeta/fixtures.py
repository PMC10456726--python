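"""Synthetic data generation: every module is testable with no download.

Public biomedical ontologies are hundreds of megabytes and version-
dependent; nothing here fetches or redistributes them.  Instead this
module generates, deterministically under a seed:

* controlled vocabularies of pronounceable multi-word terms, prefixed
  by their category name so stores are orthogonal by construction;
* typo corpora with an exact, verified edit distance;
* a small ranked-taxonomy dump exercising every species exclusion
  rule, together with its hand-derived survivor set;
* a small heading-organised descriptor dump for the tree-number
  dialect;
* the lung/ozone worked example: a freetext submission matrix, a
  store that covers every value except three deliberately missing
  terms, and the expected standardized output.

The worked example's magnitudes (ages, doses, times) are synthetic
placeholders; only its category structure, the species synonym
mapping and the three missing terms are anchored to the real study it
emulates.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .categories import get_category
from .matrix_io import SubmissionMatrix, build_schema
from .ontology import (
    DropRank,
    DropRankNameContains,
    DropRankNameWithDigits,
    DropSubtreeNameContains,
    ExtractionSpec,
)
from .standardizer import ConfirmationSet
from .vocabulary import Vocabulary, VocabularyStore, normalize_string

__all__ = [
    "FixtureConfig",
    "generate_vocabulary",
    "generate_store",
    "generate_typos",
    "generate_matrix",
    "SpeciesFixture",
    "species_rule_fixture",
    "organ_heading_fixture",
    "WorkedExample",
    "worked_example",
]

_CONSONANTS = "bcdfgklmnprstvz"
_VOWELS = "aeiou"


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the generators; identical config + seed => identical output."""

    seed: int = 0
    n_terms: int = 50
    min_words: int = 2
    max_words: int = 3
    min_syllables: int = 2
    max_syllables: int = 4
    synonym_rate: float = 0.3
    typo_edits: int = 1


def _word(rng: random.Random, config: FixtureConfig) -> str:
    n = rng.randint(config.min_syllables, config.max_syllables)
    return "".join(
        rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(n)
    )


def _term(rng: random.Random, config: FixtureConfig, prefix: str) -> str:
    n_words = rng.randint(config.min_words, config.max_words)
    return " ".join([prefix] + [_word(rng, config) for _ in range(n_words)])


def generate_vocabulary(
    category: str, config: FixtureConfig, rng: random.Random | None = None
) -> Vocabulary:
    """A vocabulary of pronounceable terms for one registered category.

    Every term starts with the (normalized) category name, so
    vocabularies generated for different categories are disjoint by
    construction.  Synonyms are abbreviated or reworded variants of
    their main term, populated at ``config.synonym_rate``.
    """
    if rng is None:
        rng = random.Random(config.seed)
    prefix = normalize_string(category)
    main_terms: set[str] = set()
    while len(main_terms) < config.n_terms:
        main_terms.add(_term(rng, config, prefix))
    synonym_map: dict[str, str] = {}
    for term in sorted(main_terms):
        if rng.random() >= config.synonym_rate:
            continue
        words = term.split()
        if rng.random() < 0.5 and len(words) > 1:
            # abbreviation: initials of all but the last word
            syn = " ".join(w[0] for w in words[:-1]) + " " + words[-1]
        else:
            syn = term + " " + _word(rng, config)
        if syn not in main_terms and syn not in synonym_map:
            synonym_map[syn] = term
    return Vocabulary(
        category=get_category(category), main_terms=main_terms, synonym_map=synonym_map
    )


def generate_store(
    categories: list[str], config: FixtureConfig
) -> VocabularyStore:
    """One generated vocabulary per category, under a single seed."""
    rng = random.Random(config.seed)
    return VocabularyStore(
        generate_vocabulary(name, config, rng) for name in categories
    )


def _levenshtein(a: str, b: str) -> int:
    # small DP used only to certify generated typos
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _one_edit(rng: random.Random, s: str) -> str:
    alphabet = _CONSONANTS + _VOWELS
    op = rng.choice(["substitute", "delete", "insert", "transpose"])
    if op == "substitute":
        i = rng.randrange(len(s))
        c = rng.choice([a for a in alphabet if a != s[i]])
        return s[:i] + c + s[i + 1 :]
    if op == "delete" and len(s) > 2:
        i = rng.randrange(len(s))
        return s[:i] + s[i + 1 :]
    if op == "insert":
        i = rng.randrange(len(s) + 1)
        return s[:i] + rng.choice(alphabet) + s[i:]
    # transpose a pair of differing adjacent characters
    pairs = [i for i in range(len(s) - 1) if s[i] != s[i + 1]]
    if not pairs:
        return s[: len(s) - 1]
    i = rng.choice(pairs)
    return s[:i] + s[i + 1] + s[i] + s[i + 2 :]


def generate_typos(
    term: str, config: FixtureConfig, count: int = 1, rng: random.Random | None = None
) -> list[str]:
    """Corrupted variants of ``term`` at exactly ``config.typo_edits`` edits.

    Each variant is certified by a Levenshtein check before being
    returned (a composition of random edits can cancel, so candidates
    are retried until the distance is exact).  Zero edits yields the
    term itself.
    """
    if len(term) < 2:
        raise ValueError("typo generation needs a term of length >= 2")
    if rng is None:
        rng = random.Random(config.seed)
    if config.typo_edits == 0:
        return [term] * count
    out: list[str] = []
    while len(out) < count:
        candidate = term
        for _ in range(config.typo_edits):
            candidate = _one_edit(rng, candidate)
        if _levenshtein(term, candidate) == config.typo_edits:
            out.append(candidate)
    return out


def generate_matrix(
    store: VocabularyStore,
    n_rows: int,
    config: FixtureConfig,
    rng: random.Random | None = None,
    *,
    p_main: float = 0.40,
    p_synonym: float = 0.20,
    p_typo: float = 0.15,
    p_new: float = 0.10,
    p_empty: float = 0.10,
    p_multi: float = 0.05,
) -> SubmissionMatrix:
    """A freetext submission matrix drawn from (and around) a store.

    Cells mix exact main terms, synonyms, typos of main terms, novel
    category-prefixed strings (future new terms), empties, and
    occasional multi-value cells.  The remaining probability mass goes
    to case/whitespace-mangled main terms.
    """
    if rng is None:
        rng = random.Random(config.seed)
    categories = ["sampleLabel"] + sorted(store.vocabularies)
    matrix = SubmissionMatrix(categories=[get_category(c) for c in categories])
    for i in range(n_rows):
        row = [f"sample{i + 1}"]
        for name in categories[1:]:
            vocab = store.vocabularies[name]
            mains = sorted(vocab.main_terms)
            term = rng.choice(mains)
            roll = rng.random()
            if roll < p_main:
                cell = term
            elif roll < p_main + p_synonym and vocab.synonym_map:
                cell = rng.choice(sorted(vocab.synonym_map))
            elif roll < p_main + p_synonym + p_typo:
                cell = generate_typos(term, config, 1, rng)[0]
            elif roll < p_main + p_synonym + p_typo + p_new:
                prefix = normalize_string(name)
                while True:
                    cell = f"{prefix} {_word(rng, config)} {_word(rng, config)}"
                    if cell not in vocab.main_terms:
                        break
            elif roll < p_main + p_synonym + p_typo + p_new + p_empty:
                cell = ""
            elif roll < p_main + p_synonym + p_typo + p_new + p_empty + p_multi:
                cell = ";".join(rng.sample(mains, min(2, len(mains))))
            else:
                cell = "  " + term.upper() + "  "
            row.append(cell)
        matrix.rows.append(row)
    return matrix


# -- taxonomy dump fixture -------------------------------------------


@dataclass(frozen=True)
class SpeciesFixture:
    """A tiny taxdump-dialect tree plus its hand-derived survivor set."""

    nodes_text: str
    names_text: str
    spec: ExtractionSpec
    expected_survivors: frozenset[str]

    def write(self, directory: str | Path) -> tuple[Path, Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nodes = directory / "nodes.dmp"
        names = directory / "names.dmp"
        nodes.write_text(self.nodes_text, encoding="utf-8")
        names.write_text(self.names_text, encoding="utf-8")
        return nodes, names


def species_rule_fixture() -> SpeciesFixture:
    """A 19-node ranked taxonomy where each exclusion rule bites.

    The tree contains one strain node, an "environmental samples"
    subtree, an "unclassified" subtree, a no-rank node with a slash, a
    species with digits, a species containing "vector", and five clean
    species.  ``expected_survivors`` was derived by applying the rules
    by hand and is frozen here as the oracle.
    """
    rows = [
        # (id, parent, rank, scientific name, [synonyms])
        ("1", "1", "no rank", "root", []),
        ("2", "1", "superkingdom", "eukaryota", []),
        ("3", "2", "family", "muridae", []),
        ("4", "3", "genus", "mus", []),
        ("5", "4", "species", "mus musculus", ["mouse", "mice", "house mouse"]),
        ("6", "5", "subspecies", "mus musculus domesticus", []),
        ("7", "5", "strain", "balb/c", []),
        ("8", "2", "genus", "homo", []),
        ("9", "8", "species", "homo sapiens", ["human"]),
        ("10", "2", "no rank", "environmental samples", []),
        ("11", "10", "species", "uncultured eukaryote", []),
        ("12", "3", "no rank", "unclassified muridae", []),
        ("13", "12", "species", "murinae sp. alpha", []),
        ("14", "2", "species", "influenza a virus 1918", []),
        ("15", "2", "species", "cloning vector lambda", []),
        ("16", "2", "no rank", "rna/dna sample group", []),
        ("17", "2", "species", "danio rerio", ["zebrafish"]),
        ("18", "2", "species", "arabidopsis thaliana", ["thale cress"]),
        ("19", "3", "species", "rattus norvegicus", ["rat", "brown rat"]),
    ]
    nodes_lines = []
    names_lines = []
    for node_id, parent, rank, name, synonyms in rows:
        nodes_lines.append(f"{node_id}\t|\t{parent}\t|\t{rank}\t|")
        names_lines.append(f"{node_id}\t|\t{name}\t|\t\t|\tscientific name\t|")
        for syn in synonyms:
            names_lines.append(f"{node_id}\t|\t{syn}\t|\t\t|\tcommon name\t|")
    spec = ExtractionSpec(
        include_roots=("1",),
        exclusions=(
            DropRank("strain"),
            DropSubtreeNameContains("environmental sample"),
            DropSubtreeNameContains("unclassified"),
            DropRankNameContains("no rank", "/"),
            DropRankNameWithDigits("species"),
            DropRankNameContains("species", "vector"),
        ),
    )
    survivors = frozenset(
        {
            "root",
            "eukaryota",
            "muridae",
            "mus",
            "mus musculus",
            "mus musculus domesticus",
            "homo",
            "homo sapiens",
            "danio rerio",
            "arabidopsis thaliana",
            "rattus norvegicus",
        }
    )
    return SpeciesFixture(
        nodes_text="\n".join(nodes_lines) + "\n",
        names_text="\n".join(names_lines) + "\n",
        spec=spec,
        expected_survivors=survivors,
    )


def organ_heading_fixture() -> str:
    """A small tree-number dialect dump (anatomy-style headings).

    Returned as TSV text; ``mouth`` carries two headings and therefore
    two parents.
    """
    lines = [
        "anatomical entity\tA\t",
        "body regions\tA01\tregions of the body",
        "head\tA01.456\tcaput",
        "respiratory system\tA04\t",
        "lung\tA04.411\tlungs;pulmo",
        "digestive system\tA14\t",
        "mouth\tA01.456.505;A14.549\toral cavity",
        "diseases\tC\t",
        "lung diseases\tC08.381\t",
    ]
    return "\n".join(lines) + "\n"


# -- worked example --------------------------------------------------


@dataclass
class WorkedExample:
    """The lung/ozone study: freetext in, standardized out.

    ``store`` covers every controlled value of ``matrix`` except
    ``allergen exposure`` (zeroTimeEvent), ``ozone`` (drugName) and
    ``hours/day`` (drugDoseUnit); ``confirmations`` adopts those three
    as new terms; ``expected_matrix`` is the hand-written standardized
    result and ``expected_new_terms`` the exact adoption set.
    """

    matrix: SubmissionMatrix
    store: VocabularyStore
    confirmations: ConfirmationSet
    expected_matrix: SubmissionMatrix
    expected_new_terms: set[tuple[str, str]] = field(default_factory=set)


def _vocab(category: str, mains: list[str], synonyms: dict[str, str]) -> Vocabulary:
    return Vocabulary(
        category=get_category(category),
        main_terms=set(mains),
        synonym_map=dict(synonyms),
    )


def default_store() -> VocabularyStore:
    """The worked example's vocabulary store (orthogonal by inspection)."""
    return VocabularyStore(
        [
            _vocab(
                "species",
                ["mus musculus", "homo sapiens", "rattus norvegicus"],
                {
                    "mouse": "mus musculus",
                    "mice": "mus musculus",
                    "house mouse": "mus musculus",
                    "human": "homo sapiens",
                    "rat": "rattus norvegicus",
                },
            ),
            _vocab("organ", ["lung", "liver", "brain"], {"lungs": "lung"}),
            _vocab("sex", ["male", "female", "hermaphrodite"], {"m": "male", "f": "female"}),
            _vocab(
                "massUnit",
                ["gram", "milligram", "kilogram"],
                {"g": "gram", "mg": "milligram", "kg": "kilogram"},
            ),
            _vocab("ageUnit", ["week", "month", "year"], {"weeks": "week", "wk": "week"}),
            _vocab("strain", ["balb/c", "c57bl/6"], {"balb/cj": "balb/c"}),
            _vocab(
                "drugName",
                ["dexamethasone", "ibuprofen", "acetaminophen"],
                {"paracetamol": "acetaminophen"},
            ),
            _vocab(
                "drugDoseUnit",
                ["part per million", "milligram per kilogram"],
                {"ppm": "part per million", "mg/kg": "milligram per kilogram"},
            ),
            _vocab("zeroTimeEvent", ["birth", "infection", "first treatment"], {}),
            _vocab(
                "timeUnit",
                ["hour", "day", "minute"],
                {"hours": "hour", "h": "hour", "days": "day"},
            ),
        ]
    )


def worked_example() -> WorkedExample:
    """The lung/ozone study as a standardization fixture.

    Adult mice of both sexes were sensitized to an allergen, exposed
    to ozone for several hours a day, and their lungs profiled some
    hours after exposure.  The freetext matrix spells species, units
    and strain the way a submitter would ("mouse", "mg", "weeks",
    "BALB/c"); the ozone treatment is represented as a drug.  Cell
    magnitudes are synthetic placeholders.
    """
    schema = build_schema(
        [
            "organ",
            "species",
            "sex",
            "age",
            "ageUnit",
            "strain",
            "mass",
            "massUnit",
            "drugName",
            "drugDoseMagnitude",
            "drugDoseUnit",
            "zeroTimeEvent",
            "time",
            "timeUnit",
        ]
    )
    header = schema.category_names
    # header order: sampleLabel, organ, species, sex, age, ageUnit,
    # strain, mass, massUnit, drugName, drugDoseMagnitude, drugDoseUnit,
    # zeroTimeEvent, time, timeUnit
    freetext_rows = [
        ["s1", "Lungs", "mouse", "Male", "8", "weeks", "BALB/c", "23.5", "mg",
         "ozone", "0.8", "hours/day", "allergen exposure", "24", "hours"],
        ["s2", "lung", "mice", "female", "8", "weeks", "BALB/c", "21.0", "mg",
         "ozone", "0.8", "hours/day", "allergen exposure", "24", "hours"],
        ["s3", "lung", "house mouse", "m", "8", "wk", "balb/cj", "22.1", "mg",
         "", "", "", "allergen exposure", "24", "h"],
        ["s4", "lungs", "mus musculus", "f", "8", "week", "balb/c", "20.7",
         "milligram", "", "", "", "allergen exposure", "24", "hour"],
    ]
    standardized_rows = [
        ["s1", "lung", "mus musculus", "male", "8", "week", "balb/c", "23.5",
         "milligram", "ozone", "0.8", "hours/day", "allergen exposure", "24", "hour"],
        ["s2", "lung", "mus musculus", "female", "8", "week", "balb/c", "21.0",
         "milligram", "ozone", "0.8", "hours/day", "allergen exposure", "24", "hour"],
        ["s3", "lung", "mus musculus", "male", "8", "week", "balb/c", "22.1",
         "milligram", "", "", "", "allergen exposure", "24", "hour"],
        ["s4", "lung", "mus musculus", "female", "8", "week", "balb/c", "20.7",
         "milligram", "", "", "", "allergen exposure", "24", "hour"],
    ]
    matrix = SubmissionMatrix(categories=list(schema.categories), rows=freetext_rows)
    expected = SubmissionMatrix(
        categories=list(schema.categories), rows=standardized_rows
    )
    assert header[0] == "sampleLabel"
    confirmations = ConfirmationSet(
        accepted_new_terms={
            ("zeroTimeEvent", "allergen exposure"): "allergen exposure",
            ("drugName", "ozone"): "ozone",
            ("drugDoseUnit", "hours/day"): "hours/day",
        }
    )
    return WorkedExample(
        matrix=matrix,
        store=default_store(),
        confirmations=confirmations,
        expected_matrix=expected,
        expected_new_terms={
            ("zeroTimeEvent", "allergen exposure"),
            ("drugName", "ozone"),
            ("drugDoseUnit", "hours/day"),
        },
    )
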