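"""Controlled vocabularies: main terms, synonyms, and the store invariants.

A :class:`Vocabulary` holds the allowed strings for one controlled
category.  Each concept has exactly one *main term* (the canonical
surface, e.g. ``"mus musculus"``) and any number of *synonyms*
(``"mouse"``, ``"mice"``, ``"house mouse"``) that map many-to-one onto
it.  A :class:`VocabularyStore` holds the vocabularies of all
controlled categories and maintains orthogonality: no string is a main
term of two different categories, so a standardized value identifies
its category by string equality alone.

All stored strings are in normalized form (lowercase, whitespace
collapsed); see :func:`normalize_string`.  Vocabularies carry an
integer version that is bumped on every mutation so that fitted
matcher models can detect staleness.

Persistence is one TSV file per category with columns
``term  role  maps_to`` (``role`` in ``{main, synonym}``; ``maps_to``
empty for main rows), plus a JSON manifest listing every category with
its grouping and value class.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

from .categories import REGISTRY, CategorySpec, Grouping, ValueClass, get_category
from .errors import (
    CategoryError,
    OrthogonalityError,
    RedundancyError,
    VocabularyParseError,
)

__all__ = [
    "normalize_string",
    "Vocabulary",
    "VocabularyStore",
    "LookupResult",
    "Violation",
    "validate_store",
    "save_vocab",
    "load_vocab",
]


def normalize_string(s: str) -> str:
    """Normalize a raw surface string for storage and comparison.

    Lowercases, strips leading/trailing whitespace and collapses every
    internal whitespace run to a single space.  Punctuation is kept:
    it is significant in strain names (``balb/c``) and compound units
    (``hours/day``).  The empty string maps to itself.
    """
    return " ".join(s.lower().split())


@dataclass(frozen=True)
class LookupResult:
    """Outcome of a vocabulary lookup.

    ``kind`` is ``"main"`` (the query is itself a main term),
    ``"synonym"`` (mapped onto ``term``) or ``"miss"`` (``term`` is
    ``None``).
    """

    kind: Literal["main", "synonym", "miss"]
    term: str | None

    def __bool__(self) -> bool:
        return self.kind != "miss"


@dataclass
class Vocabulary:
    """The controlled term set of one metadata category."""

    category: CategorySpec
    main_terms: set[str] = field(default_factory=set)
    synonym_map: dict[str, str] = field(default_factory=dict)
    version: int = 0

    def surfaces(self) -> Iterator[tuple[str, str]]:
        """Yield ``(surface, main_term)`` for every main term and synonym.

        Main terms map to themselves.  Order is deterministic (sorted
        mains, then sorted synonyms).
        """
        for term in sorted(self.main_terms):
            yield term, term
        for syn in sorted(self.synonym_map):
            yield syn, self.synonym_map[syn]

    def lookup(self, s: str) -> LookupResult:
        q = normalize_string(s)
        if q in self.main_terms:
            return LookupResult("main", q)
        if q in self.synonym_map:
            return LookupResult("synonym", self.synonym_map[q])
        return LookupResult("miss", None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Vocabulary):
            return NotImplemented
        return (
            self.category == other.category
            and self.main_terms == other.main_terms
            and self.synonym_map == other.synonym_map
        )


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_store`."""

    kind: Literal["overlap", "redundancy", "dangling", "denormalized"]
    categories: tuple[str, ...]
    term: str

    def __str__(self) -> str:
        cats = " / ".join(self.categories)
        return f"{self.kind}: {self.term!r} in {cats}"


class VocabularyStore:
    """All controlled vocabularies together, kept pairwise orthogonal."""

    def __init__(self, vocabularies: Iterable[Vocabulary] = ()):
        self.vocabularies: dict[str, Vocabulary] = {}
        for vocab in vocabularies:
            self.add_vocabulary(vocab)

    # -- structure ---------------------------------------------------

    def add_vocabulary(self, vocab: Vocabulary) -> None:
        if not vocab.category.is_controlled:
            raise CategoryError(
                f"category {vocab.category.name!r} is "
                f"{vocab.category.value_class.value}, not controlled"
            )
        if vocab.category.name in self.vocabularies:
            raise CategoryError(f"duplicate category {vocab.category.name!r}")
        for other in self.vocabularies.values():
            clash = vocab.main_terms & other.main_terms
            if clash:
                raise OrthogonalityError(
                    sorted(clash)[0], vocab.category.name, other.category.name
                )
        self.vocabularies[vocab.category.name] = vocab

    def __contains__(self, category: str) -> bool:
        return category in self.vocabularies

    def __getitem__(self, category: str) -> Vocabulary:
        return self._get(category)

    def _get(self, category: str) -> Vocabulary:
        try:
            return self.vocabularies[category]
        except KeyError:
            raise CategoryError(
                f"no controlled vocabulary for category {category!r}"
            ) from None

    def categories(self) -> list[str]:
        return sorted(self.vocabularies)

    def versions(self) -> dict[str, int]:
        return {name: v.version for name, v in self.vocabularies.items()}

    # -- queries -----------------------------------------------------

    def lookup(self, category: str, s: str) -> LookupResult:
        """Resolve a raw string against one category's vocabulary."""
        return self._get(category).lookup(s)

    def owner_of_main_term(self, term: str) -> str | None:
        """Return the category owning ``term`` as a main term, if any."""
        q = normalize_string(term)
        for name, vocab in self.vocabularies.items():
            if q in vocab.main_terms:
                return name
        return None

    # -- mutation ----------------------------------------------------

    def add_main_term(self, category: str, s: str) -> bool:
        """Add a main term; returns True if the store changed.

        Adding a term already present in the same category is a no-op
        (version unchanged).  Adding a term owned by a *different*
        category raises :class:`OrthogonalityError`.
        """
        vocab = self._get(category)
        term = normalize_string(s)
        if not term:
            raise ValueError("empty string cannot be a main term")
        if term in vocab.main_terms:
            return False
        owner = self.owner_of_main_term(term)
        if owner is not None:
            raise OrthogonalityError(term, category, owner)
        vocab.main_terms.add(term)
        # a synonym promoted to main term stops being a synonym
        vocab.synonym_map.pop(term, None)
        vocab.version += 1
        return True

    def add_synonym(self, category: str, synonym: str, main: str) -> bool:
        """Map a synonym onto an existing main term of the category."""
        vocab = self._get(category)
        syn = normalize_string(synonym)
        target = normalize_string(main)
        if not syn:
            raise ValueError("empty string cannot be a synonym")
        if target not in vocab.main_terms:
            raise ValueError(
                f"cannot add synonym {syn!r}: {target!r} is not a main term "
                f"of {category!r}"
            )
        if syn in vocab.main_terms:
            raise RedundancyError(
                f"{syn!r} is already a main term of {category!r}; "
                "a synonym may not shadow a main term"
            )
        if vocab.synonym_map.get(syn) == target:
            return False
        vocab.synonym_map[syn] = target
        vocab.version += 1
        return True


def validate_store(store: VocabularyStore) -> list[Violation]:
    """Check every store invariant; an empty list means valid.

    Reports pairwise main-term overlaps between categories, synonyms
    shadowing a same-category main term, synonyms mapping to an absent
    main term, and strings stored in non-normalized form.
    """
    violations: list[Violation] = []
    names = sorted(store.vocabularies)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            overlap = store.vocabularies[a].main_terms & store.vocabularies[b].main_terms
            for term in sorted(overlap):
                violations.append(Violation("overlap", (a, b), term))
    for name in names:
        vocab = store.vocabularies[name]
        for syn, target in sorted(vocab.synonym_map.items()):
            if syn in vocab.main_terms:
                violations.append(Violation("redundancy", (name,), syn))
            if target not in vocab.main_terms:
                violations.append(Violation("dangling", (name,), syn))
        for s in sorted(vocab.main_terms | set(vocab.synonym_map)):
            if s != normalize_string(s):
                violations.append(Violation("denormalized", (name,), s))
    return violations


# -- persistence -----------------------------------------------------

_TSV_HEADER = ["term", "role", "maps_to"]


def save_vocab(vocab: Vocabulary, path: str | Path) -> None:
    """Write one vocabulary as a three-column TSV (term, role, maps_to)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_HEADER)
        for surface, main in vocab.surfaces():
            if surface == main and surface in vocab.main_terms:
                writer.writerow([surface, "main", ""])
            else:
                writer.writerow([surface, "synonym", main])


def load_vocab(path: str | Path, category: CategorySpec) -> Vocabulary:
    """Read a vocabulary TSV written by :func:`save_vocab`.

    Raises :class:`VocabularyParseError` with the offending 1-based
    line number on malformed roles, dangling synonym targets or
    duplicate term rows.
    """
    main_terms: set[str] = set()
    synonym_rows: list[tuple[int, str, str]] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise VocabularyParseError("empty vocabulary file", line=1) from None
        if header != _TSV_HEADER:
            raise VocabularyParseError(
                f"expected header {_TSV_HEADER}, got {header}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise VocabularyParseError(
                    f"expected 3 columns, got {len(row)}", line=lineno
                )
            term, role, maps_to = (normalize_string(c) for c in row)
            if not term:
                raise VocabularyParseError("empty term", line=lineno)
            if term in seen:
                raise VocabularyParseError(f"duplicate term {term!r}", line=lineno)
            seen.add(term)
            if role == "main":
                if maps_to:
                    raise VocabularyParseError(
                        f"main row {term!r} must have empty maps_to", line=lineno
                    )
                main_terms.add(term)
            elif role == "synonym":
                if not maps_to:
                    raise VocabularyParseError(
                        f"synonym row {term!r} lacks maps_to", line=lineno
                    )
                synonym_rows.append((lineno, term, maps_to))
            else:
                raise VocabularyParseError(f"unknown role {role!r}", line=lineno)
    synonym_map: dict[str, str] = {}
    for lineno, syn, target in synonym_rows:
        if target not in main_terms:
            raise VocabularyParseError(
                f"synonym {syn!r} maps to absent main term {target!r}", line=lineno
            )
        if syn in main_terms:
            raise VocabularyParseError(
                f"synonym {syn!r} shadows a main term", line=lineno
            )
        synonym_map[syn] = target
    return Vocabulary(category=category, main_terms=main_terms, synonym_map=synonym_map)


def save_store(store: VocabularyStore, directory: str | Path) -> None:
    """Write every vocabulary TSV plus a ``manifest.json`` into a directory.

    The manifest lists each category with its grouping and value class
    and is the machine-readable schema of the store.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for name in sorted(store.vocabularies):
        vocab = store.vocabularies[name]
        save_vocab(vocab, directory / f"{name}.tsv")
        manifest[name] = {
            "grouping": vocab.category.grouping.value,
            "value_class": vocab.category.value_class.value,
        }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_store(directory: str | Path) -> VocabularyStore:
    """Load a store previously written by :func:`save_store`."""
    directory = Path(directory)
    with open(directory / "manifest.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    store = VocabularyStore()
    for name in sorted(manifest):
        entry = manifest[name]
        if name in REGISTRY:
            category = get_category(name)
        else:
            category = CategorySpec(
                name, Grouping(entry["grouping"]), ValueClass(entry["value_class"])
            )
        store.add_vocabulary(load_vocab(directory / f"{name}.tsv", category))
    return store
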