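"""Submission matrices: schema building, CSV reading/writing, validation.

A submission matrix is the worksheet a study submitter fills in: one
row per sample, one column per registered metadata category, cells in
freetext.  Schema building is the first half of the user flow — pick
at least one core sample type plus any further attributes, and get
back an empty template whose header order is fixed (``sampleLabel``
first, then core sample types, sample description, study factors,
time series, other, preserving the user's order within each group).

CSV is RFC 4180 (as produced by the stdlib ``csv`` module), UTF-8,
header row first.  Cells pass through verbatim — normalization is the
standardizer's job, which must be able to report originals.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .categories import (
    CORE_SAMPLE_TYPES,
    GROUP_ORDER,
    REGISTRY,
    UNIT_PARTNERS,
    CategorySpec,
)
from .errors import MatrixValidationError

__all__ = ["SubmissionMatrix", "build_schema", "read_csv", "write_csv"]


@dataclass
class SubmissionMatrix:
    """An ordered set of categories with per-sample freetext cells.

    ``rows[i][j]`` is the raw cell of sample ``i`` in category
    ``categories[j]``.  Multi-value cells use ``";"`` as delimiter.
    """

    categories: list[CategorySpec]
    rows: list[list[str]] = field(default_factory=list)

    @property
    def category_names(self) -> list[str]:
        return [c.name for c in self.categories]

    def column_index(self, name: str) -> int:
        try:
            return self.category_names.index(name)
        except ValueError:
            raise MatrixValidationError(f"matrix has no category {name!r}") from None

    def validate(self) -> None:
        """Structural checks: known headers, label column, row lengths."""
        names = self.category_names
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise MatrixValidationError(f"duplicate headers: {dupes}")
        unknown = [n for n in names if n not in REGISTRY]
        if unknown:
            raise MatrixValidationError(f"unknown headers: {unknown}")
        if "sampleLabel" not in names:
            raise MatrixValidationError("matrix lacks the required sampleLabel column")
        label_col = names.index("sampleLabel")
        for i, row in enumerate(self.rows):
            if len(row) != len(names):
                raise MatrixValidationError(
                    f"row {i + 1}: expected {len(names)} cells, got {len(row)}"
                )
            if not row[label_col].strip():
                raise MatrixValidationError(f"row {i + 1}: empty sampleLabel")


def build_schema(selection: Sequence[str]) -> SubmissionMatrix:
    """Build an empty submission template from a category selection.

    ``selection`` is the user's ordered pick of categories (not
    including ``sampleLabel``, which is always present and first).  At
    least one core sample type is required; a unit category may only
    be selected together with its magnitude partner.
    """
    if not selection:
        raise MatrixValidationError("empty schema selection")
    seen: set[str] = set()
    for name in selection:
        if name not in REGISTRY:
            raise MatrixValidationError(f"unknown category in selection: {name!r}")
        if name in seen:
            raise MatrixValidationError(f"duplicate category in selection: {name!r}")
        seen.add(name)
    if not any(name in CORE_SAMPLE_TYPES for name in selection):
        raise MatrixValidationError(
            f"selection must include at least one core sample type "
            f"{CORE_SAMPLE_TYPES}"
        )
    for unit, magnitude in UNIT_PARTNERS.items():
        if unit in seen and magnitude not in seen:
            raise MatrixValidationError(
                f"{unit!r} selected without its magnitude partner {magnitude!r}"
            )
    ordered: list[CategorySpec] = [REGISTRY["sampleLabel"]]
    for grouping in GROUP_ORDER:
        for name in selection:
            spec = REGISTRY[name]
            if spec.grouping is grouping and name != "sampleLabel":
                ordered.append(spec)
    return SubmissionMatrix(categories=ordered, rows=[])


def schema_to_json(matrix: SubmissionMatrix) -> str:
    """The schema as JSON: ordered categories with groupings and classes."""
    return json.dumps(
        [
            {
                "name": c.name,
                "grouping": c.grouping.value,
                "value_class": c.value_class.value,
            }
            for c in matrix.categories
        ],
        indent=2,
    )


def read_csv(source: str | Path | io.TextIOBase) -> SubmissionMatrix:
    """Parse and validate a submission matrix CSV.

    Headers must all be registered categories; ragged rows, duplicate
    or unknown headers and a missing ``sampleLabel`` column are
    errors.  Line endings are normalized on read.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8", newline="") as fh:
            return read_csv(fh)
    reader = csv.reader(source)
    try:
        header = next(reader)
    except StopIteration:
        raise MatrixValidationError("empty CSV: no header row") from None
    rows = [row for row in reader]
    try:
        categories = [REGISTRY[name] for name in header]
    except KeyError:
        unknown = [n for n in header if n not in REGISTRY]
        raise MatrixValidationError(f"unknown headers: {unknown}") from None
    matrix = SubmissionMatrix(categories=categories, rows=rows)
    matrix.validate()
    return matrix


def write_csv(matrix: SubmissionMatrix, target: str | Path | io.TextIOBase) -> None:
    """Write a submission matrix as RFC 4180 CSV with ``\\n`` line endings."""
    if isinstance(target, (str, Path)):
        with open(target, "w", encoding="utf-8", newline="") as fh:
            write_csv(matrix, fh)
            return
    writer = csv.writer(target, lineterminator="\n")
    writer.writerow(matrix.category_names)
    writer.writerows(matrix.rows)
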