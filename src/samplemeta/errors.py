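"""Exception hierarchy shared across the package."""

from __future__ import annotations


class SampleMetaError(Exception):
    """Base class for all package errors."""


class CategoryError(SampleMetaError):
    """Unknown category, or an operation on a non-controlled category."""


class OrthogonalityError(SampleMetaError):
    """A main term would appear in two different controlled vocabularies."""

    def __init__(self, term: str, category: str, clashing_category: str):
        self.term = term
        self.category = category
        self.clashing_category = clashing_category
        super().__init__(
            f"term {term!r} cannot be a main term of {category!r}: "
            f"it is already a main term of {clashing_category!r}"
        )


class RedundancyError(SampleMetaError):
    """A synonym would shadow a main term of the same vocabulary."""


class VocabularyParseError(SampleMetaError):
    """Malformed vocabulary TSV; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class OntologyParseError(SampleMetaError):
    """Malformed ontology dump file."""


class MatrixValidationError(SampleMetaError):
    """A submission matrix violates structural rules (headers, rows, cells)."""


class ModelVersionMismatch(SampleMetaError):
    """A matcher model is stale relative to its vocabulary; retrain required."""
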