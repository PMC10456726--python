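"""Three-pass standardization of a freetext submission matrix.

The pipeline converts every cell of a submission matrix into
vocabulary-controlled form and records, per value, which pass
resolved it:

1. **Automatic pass** — exact main-term and synonym lookups, then
   trigram tf-idf nearest-neighbor matching.  Matches at or above the
   accept threshold are applied automatically; weaker matches become
   proposals; numeric cells are validated as numbers and passed
   through; freetext cells pass through untouched.
2. **Substring pass** — values still unresolved are searched as
   substrings of vocabulary surfaces (and vice versa); hits only ever
   become proposals, never automatic.
3. **New-term pass** — every remaining value needs an explicit
   confirmation: either a chosen proposal, or adoption as a new main
   term of its category (orthogonality enforced), after which the
   affected matcher models are refitted.

After a successful run every non-empty controlled value in the output
is a main term of the updated store — the pipeline's guarantee — and
a second run is the identity, resolving everything in pass one as
exact hits with no vocabulary mutation.  Vocabulary mutations are
all-or-nothing: the caller's store is never touched unless the whole
call succeeds.

Cells may hold several values separated by ``";"``; each delimited
value is curated independently and the finals are rejoined in input
order.  Freetext cells are never split (a comment may legitimately
contain semicolons).
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Literal

from .categories import ValueClass
from .errors import MatrixValidationError, ModelVersionMismatch
from .matcher import (
    DEFAULT_ACCEPT_THRESHOLD,
    DEFAULT_PROPOSE_THRESHOLD,
    TrigramModel,
    fit,
    nearest,
    substring_match,
)
from .matrix_io import SubmissionMatrix
from .vocabulary import VocabularyStore, normalize_string

__all__ = [
    "CurationEntry",
    "CurationReport",
    "ConfirmationSet",
    "PendingValue",
    "ConfirmationRequired",
    "StandardizationResult",
    "fit_models",
    "classify_cell",
    "standardize",
    "auto_confirm",
    "verify_guarantee",
]

Pass = Literal[
    "exact",
    "synonym",
    "nn_auto",
    "nn_confirmed",
    "substring",
    "new_term",
    "passthrough",
    "empty",
]

#: Plain decimal or scientific notation; comma decimals are rejected.
_NUMERIC_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


@dataclass(frozen=True)
class CurationEntry:
    """How one delimited value of one cell was resolved."""

    row: int
    category: str
    value_index: int
    original: str
    pass_: Pass
    final: str
    similarity: float | None = None


@dataclass
class CurationReport:
    entries: list[CurationEntry] = field(default_factory=list)
    #: (category, term) pairs actually added to the store by pass three.
    new_terms: list[tuple[str, str]] = field(default_factory=list)

    def by_pass(self, pass_: Pass) -> list[CurationEntry]:
        return [e for e in self.entries if e.pass_ == pass_]

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "row": e.row,
                    "category": e.category,
                    "value_index": e.value_index,
                    "original": e.original,
                    "pass": e.pass_,
                    "final": e.final,
                    "similarity": e.similarity,
                }
                for e in self.entries
            ],
            "new_terms": [list(t) for t in self.new_terms],
        }


@dataclass(frozen=True)
class Proposal:
    term: str
    surface: str
    source: Literal["nn", "substring"]
    similarity: float | None


@dataclass
class PendingValue:
    """An unresolved value awaiting user confirmation."""

    row: int
    category: str
    value_index: int
    original: str
    proposals: list[Proposal] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "row": self.row,
            "category": self.category,
            "value_index": self.value_index,
            "original": self.original,
            "proposals": [
                {
                    "term": p.term,
                    "surface": p.surface,
                    "source": p.source,
                    "similarity": p.similarity,
                }
                for p in self.proposals
            ],
        }


class ConfirmationRequired(MatrixValidationError):
    """Pass three cannot finish: these values need user confirmation."""

    def __init__(self, pending: list[PendingValue]):
        self.pending = pending
        listed = ", ".join(
            f"({p.category!r}, {p.original!r})" for p in pending[:10]
        )
        more = "" if len(pending) <= 10 else f" and {len(pending) - 10} more"
        super().__init__(f"unconfirmed values: {listed}{more}")


class ConfirmationSet:
    """User decisions for pending values.

    ``accepted_proposals`` maps ``(category, original)`` to the chosen
    main term; ``accepted_new_terms`` maps ``(category, original)`` to
    the final new-term string (typically the original itself).  Keys
    are normalized internally and must be disjoint between the maps.
    """

    def __init__(
        self,
        accepted_proposals: dict[tuple[str, str], str] | None = None,
        accepted_new_terms: dict[tuple[str, str], str] | None = None,
    ):
        self.accepted_proposals = {
            (cat, normalize_string(orig)): normalize_string(term)
            for (cat, orig), term in (accepted_proposals or {}).items()
        }
        self.accepted_new_terms = {
            (cat, normalize_string(orig)): normalize_string(term)
            for (cat, orig), term in (accepted_new_terms or {}).items()
        }
        clash = set(self.accepted_proposals) & set(self.accepted_new_terms)
        if clash:
            raise ValueError(
                f"confirmations both accept a proposal and a new term for {sorted(clash)}"
            )

    @classmethod
    def from_dict(cls, data: dict) -> "ConfirmationSet":
        def parse(entries: list[dict]) -> dict[tuple[str, str], str]:
            return {
                (e["category"], e["original"]): e["final"] for e in entries
            }

        return cls(
            accepted_proposals=parse(data.get("accepted_proposals", [])),
            accepted_new_terms=parse(data.get("accepted_new_terms", [])),
        )

    def to_dict(self) -> dict:
        def dump(mapping: dict[tuple[str, str], str]) -> list[dict]:
            return [
                {"category": cat, "original": orig, "final": final}
                for (cat, orig), final in sorted(mapping.items())
            ]

        return {
            "accepted_proposals": dump(self.accepted_proposals),
            "accepted_new_terms": dump(self.accepted_new_terms),
        }


@dataclass
class StandardizationResult:
    matrix: SubmissionMatrix
    report: CurationReport
    store: VocabularyStore
    models: dict[str, TrigramModel]


def classify_cell(category) -> ValueClass:
    """The value class deciding how a category's cells are curated."""
    return category.value_class


def fit_models(store: VocabularyStore) -> dict[str, TrigramModel]:
    """Fit one trigram model per controlled category of the store."""
    return {name: fit(store.vocabularies[name]) for name in store.vocabularies}


def _check_model_versions(
    store: VocabularyStore, models: dict[str, TrigramModel]
) -> None:
    for name, vocab in store.vocabularies.items():
        model = models.get(name)
        if model is None:
            raise ModelVersionMismatch(f"no fitted model for category {name!r}")
        if model.vocab_versions.get(name) != vocab.version:
            raise ModelVersionMismatch(
                f"model for {name!r} was fitted on version "
                f"{model.vocab_versions.get(name)}, store is at {vocab.version}; "
                "retrain required"
            )


def standardize(
    matrix: SubmissionMatrix,
    store: VocabularyStore,
    models: dict[str, TrigramModel] | None = None,
    confirmations: ConfirmationSet | None = None,
    *,
    accept_threshold: float = DEFAULT_ACCEPT_THRESHOLD,
    propose_threshold: float = DEFAULT_PROPOSE_THRESHOLD,
    k: int = 5,
) -> StandardizationResult:
    """Run the three-pass pipeline on a submission matrix.

    Raises :class:`ConfirmationRequired` (listing pending values and
    their proposals) when values remain unresolved and ``confirmations``
    does not cover them.  On success returns the standardized matrix,
    the curation report, the (possibly expanded) store copy and the
    refitted models; the caller's store and models are never mutated.
    """
    matrix.validate()
    work_store = copy.deepcopy(store)
    if models is None:
        models = fit_models(work_store)
    else:
        _check_model_versions(work_store, models)
    confirmations = confirmations or ConfirmationSet()

    entries: dict[tuple[int, int, int], CurationEntry] = {}
    pending: list[PendingValue] = []
    # split every cell once; freetext cells are a single value
    cell_values: dict[tuple[int, int], list[str]] = {}

    def record(entry: CurationEntry, col: int) -> None:
        entries[(entry.row, col, entry.value_index)] = entry

    # -- pass 1: exact / synonym / nearest-neighbor ------------------
    for i, row in enumerate(matrix.rows):
        for j, spec in enumerate(matrix.categories):
            cell = row[j]
            klass = classify_cell(spec)
            if not cell.strip():
                cell_values[(i, j)] = [cell]
                record(CurationEntry(i, spec.name, 0, cell, "empty", ""), j)
                continue
            if klass is ValueClass.FREETEXT:
                cell_values[(i, j)] = [cell]
                record(CurationEntry(i, spec.name, 0, cell, "passthrough", cell), j)
                continue
            values = cell.split(";")
            cell_values[(i, j)] = values
            for v, piece in enumerate(values):
                stripped = piece.strip()
                if not stripped:
                    record(CurationEntry(i, spec.name, v, piece, "empty", ""), j)
                    continue
                if klass is ValueClass.NUMERIC:
                    if not _NUMERIC_RE.match(stripped):
                        raise MatrixValidationError(
                            f"row {i + 1}, category {spec.name!r}: "
                            f"{stripped!r} is not a number"
                        )
                    record(
                        CurationEntry(i, spec.name, v, piece, "passthrough", stripped),
                        j,
                    )
                    continue
                # controlled
                hit = work_store.lookup(spec.name, stripped)
                if hit.kind == "main":
                    record(
                        CurationEntry(i, spec.name, v, piece, "exact", hit.term, 1.0), j
                    )
                    continue
                if hit.kind == "synonym":
                    record(
                        CurationEntry(i, spec.name, v, piece, "synonym", hit.term, 1.0),
                        j,
                    )
                    continue
                result = nearest(
                    models[spec.name],
                    stripped,
                    k,
                    accept_threshold=accept_threshold,
                    propose_threshold=propose_threshold,
                )
                if result.decision == "auto":
                    best = result.best
                    record(
                        CurationEntry(
                            i, spec.name, v, piece, "nn_auto", best.term, best.similarity
                        ),
                        j,
                    )
                    continue
                proposals = [
                    Proposal(c.term, c.surface, "nn", c.similarity)
                    for c in result.candidates
                    if c.similarity >= propose_threshold
                ]
                pending.append(PendingValue(i, spec.name, v, piece, proposals))

    # -- pass 2: substring rescue (proposals only) -------------------
    for p in pending:
        already = {prop.term for prop in p.proposals}
        for hit in substring_match(work_store.vocabularies[p.category], p.original):
            if hit.term not in already:
                p.proposals.append(
                    Proposal(hit.term, hit.surface, "substring", None)
                )
                already.add(hit.term)

    # -- pass 3: confirmations and new terms -------------------------
    missing = [
        p
        for p in pending
        if (p.category, normalize_string(p.original)) not in confirmations.accepted_proposals
        and (p.category, normalize_string(p.original)) not in confirmations.accepted_new_terms
    ]
    if missing:
        raise ConfirmationRequired(missing)

    report = CurationReport()
    mutated: set[str] = set()
    for p in pending:
        key = (p.category, normalize_string(p.original))
        col = matrix.column_index(p.category)
        if key in confirmations.accepted_proposals:
            chosen = confirmations.accepted_proposals[key]
            if chosen not in work_store.vocabularies[p.category].main_terms:
                raise MatrixValidationError(
                    f"confirmed proposal {chosen!r} is not a main term of "
                    f"{p.category!r}"
                )
            source = next(
                (prop for prop in p.proposals if prop.term == chosen), None
            )
            if source is not None and source.source == "substring":
                pass_: Pass = "substring"
                similarity = source.similarity
            else:
                pass_ = "nn_confirmed"
                similarity = source.similarity if source is not None else None
            record(
                CurationEntry(
                    p.row, p.category, p.value_index, p.original, pass_, chosen, similarity
                ),
                col,
            )
        else:
            final = confirmations.accepted_new_terms[key]
            if not final:
                raise MatrixValidationError(
                    f"empty new-term confirmation for ({p.category!r}, {p.original!r})"
                )
            if work_store.add_main_term(p.category, final):
                if (p.category, final) not in report.new_terms:
                    report.new_terms.append((p.category, final))
                mutated.add(p.category)
            record(
                CurationEntry(
                    p.row, p.category, p.value_index, p.original, "new_term", final
                ),
                col,
            )

    models = dict(models)
    for name in mutated:
        models[name] = fit(work_store.vocabularies[name])

    # -- assemble output ---------------------------------------------
    out_rows: list[list[str]] = []
    for i, row in enumerate(matrix.rows):
        out_row: list[str] = []
        for j, _spec in enumerate(matrix.categories):
            values = cell_values[(i, j)]
            finals = [entries[(i, j, v)].final for v in range(len(values))]
            out_row.append(";".join(finals))
        out_rows.append(out_row)
    report.entries = [entries[key] for key in sorted(entries)]
    out_matrix = SubmissionMatrix(categories=list(matrix.categories), rows=out_rows)
    return StandardizationResult(out_matrix, report, work_store, models)


def auto_confirm(
    pending: list[PendingValue],
    policy: Literal["best_proposal", "new_term"] = "best_proposal",
) -> ConfirmationSet:
    """Build a confirmation set accepting every pending value.

    ``best_proposal`` takes the top proposal when one exists and falls
    back to adopting the original as a new term; ``new_term`` always
    adopts the original.  This is the non-interactive stand-in for the
    confirmation step of an interactive frontend.
    """
    proposals: dict[tuple[str, str], str] = {}
    new_terms: dict[tuple[str, str], str] = {}
    for p in pending:
        key = (p.category, p.original)
        if policy == "best_proposal" and p.proposals:
            proposals[key] = p.proposals[0].term
        else:
            new_terms[key] = p.original
    return ConfirmationSet(accepted_proposals=proposals, accepted_new_terms=new_terms)


def verify_guarantee(
    matrix: SubmissionMatrix, store: VocabularyStore
) -> list[tuple[int, str, str]]:
    """Violations of the standardization guarantee, as (row, category, value).

    A standardized matrix must have every non-empty delimited value of
    every controlled column equal to a main term of that category's
    vocabulary.  An empty list means the matrix is standardized.
    """
    violations: list[tuple[int, str, str]] = []
    for j, spec in enumerate(matrix.categories):
        if not spec.is_controlled:
            continue
        vocab = store.vocabularies.get(spec.name)
        terms = vocab.main_terms if vocab is not None else set()
        for i, row in enumerate(matrix.rows):
            for piece in row[j].split(";"):
                if piece.strip() and piece not in terms:
                    violations.append((i, spec.name, piece))
    return violations
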