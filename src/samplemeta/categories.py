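"""Registry of sample-metadata categories.

Every column that may appear in a submission matrix is a registered
*category*.  A category belongs to one of five groupings (core sample
type, sample description, study factors, time series, other) and has a
value class that decides how its cells are curated:

``controlled``
    cells must end up as main terms of the category's vocabulary;
``numeric``
    cells are magnitudes (mass, age, dose ...) that are validated as
    numbers but never vocabulary-matched;
``freetext``
    cells pass through untouched (labels, inclusion/exclusion criteria,
    comments).

Unit categories (``massUnit``, ``ageUnit`` ...) are controlled and are
only meaningful next to their magnitude partner, which schema building
enforces.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass


class Grouping(enum.Enum):
    CORE_SAMPLE_TYPE = "CoreSampleType"
    SAMPLE_DESCRIPTION = "SampleDescription"
    STUDY_FACTORS = "StudyFactors"
    TIME_SERIES = "TimeSeries"
    OTHER = "Other"


class ValueClass(enum.Enum):
    CONTROLLED = "controlled"
    NUMERIC = "numeric"
    FREETEXT = "freetext"


@dataclass(frozen=True)
class CategorySpec:
    """One metadata category: its name, grouping, and value class."""

    name: str
    grouping: Grouping
    value_class: ValueClass

    @property
    def is_controlled(self) -> bool:
        return self.value_class is ValueClass.CONTROLLED


def _c(name: str, grouping: Grouping, value_class: ValueClass) -> CategorySpec:
    return CategorySpec(name, grouping, value_class)


#: Canonical category registry, in canonical within-grouping order.
REGISTRY: dict[str, CategorySpec] = {
    spec.name: spec
    for spec in [
        _c("sampleLabel", Grouping.OTHER, ValueClass.FREETEXT),
        # core sample types
        _c("species", Grouping.CORE_SAMPLE_TYPE, ValueClass.CONTROLLED),
        _c("organ", Grouping.CORE_SAMPLE_TYPE, ValueClass.CONTROLLED),
        _c("cellLine", Grouping.CORE_SAMPLE_TYPE, ValueClass.CONTROLLED),
        _c("material", Grouping.CORE_SAMPLE_TYPE, ValueClass.CONTROLLED),
        # sample description
        _c("mass", Grouping.SAMPLE_DESCRIPTION, ValueClass.NUMERIC),
        _c("massUnit", Grouping.SAMPLE_DESCRIPTION, ValueClass.CONTROLLED),
        _c("volume", Grouping.SAMPLE_DESCRIPTION, ValueClass.NUMERIC),
        _c("volumeUnit", Grouping.SAMPLE_DESCRIPTION, ValueClass.CONTROLLED),
        _c("sex", Grouping.SAMPLE_DESCRIPTION, ValueClass.CONTROLLED),
        _c("height", Grouping.SAMPLE_DESCRIPTION, ValueClass.NUMERIC),
        _c("heightUnit", Grouping.SAMPLE_DESCRIPTION, ValueClass.CONTROLLED),
        _c("weight", Grouping.SAMPLE_DESCRIPTION, ValueClass.NUMERIC),
        _c("weightUnit", Grouping.SAMPLE_DESCRIPTION, ValueClass.CONTROLLED),
        _c("age", Grouping.SAMPLE_DESCRIPTION, ValueClass.NUMERIC),
        _c("ageUnit", Grouping.SAMPLE_DESCRIPTION, ValueClass.CONTROLLED),
        _c("ethnicity", Grouping.SAMPLE_DESCRIPTION, ValueClass.CONTROLLED),
        _c("geographicalOrigin", Grouping.SAMPLE_DESCRIPTION, ValueClass.CONTROLLED),
        _c("strain", Grouping.SAMPLE_DESCRIPTION, ValueClass.CONTROLLED),
        # study factors
        _c("drugName", Grouping.STUDY_FACTORS, ValueClass.CONTROLLED),
        _c("drugDoseMagnitude", Grouping.STUDY_FACTORS, ValueClass.NUMERIC),
        _c("drugDoseUnit", Grouping.STUDY_FACTORS, ValueClass.CONTROLLED),
        _c("geneKnockout", Grouping.STUDY_FACTORS, ValueClass.CONTROLLED),
        _c("disease", Grouping.STUDY_FACTORS, ValueClass.CONTROLLED),
        _c("diet", Grouping.STUDY_FACTORS, ValueClass.CONTROLLED),
        _c("exercise", Grouping.STUDY_FACTORS, ValueClass.CONTROLLED),
        # time series
        _c("zeroTimeEvent", Grouping.TIME_SERIES, ValueClass.CONTROLLED),
        _c("time", Grouping.TIME_SERIES, ValueClass.NUMERIC),
        _c("timeUnit", Grouping.TIME_SERIES, ValueClass.CONTROLLED),
        # other (freetext escape hatches)
        _c("inclusion", Grouping.OTHER, ValueClass.FREETEXT),
        _c("exclusion", Grouping.OTHER, ValueClass.FREETEXT),
        _c("comment", Grouping.OTHER, ValueClass.FREETEXT),
    ]
}

#: Core sample types; a schema must select at least one.
CORE_SAMPLE_TYPES = ("species", "organ", "cellLine", "material")

#: Unit category -> required magnitude partner.
UNIT_PARTNERS: dict[str, str] = {
    "massUnit": "mass",
    "volumeUnit": "volume",
    "heightUnit": "height",
    "weightUnit": "weight",
    "ageUnit": "age",
    "drugDoseUnit": "drugDoseMagnitude",
    "timeUnit": "time",
}

#: Header ordering of groupings in built schemas.
GROUP_ORDER = (
    Grouping.CORE_SAMPLE_TYPE,
    Grouping.SAMPLE_DESCRIPTION,
    Grouping.STUDY_FACTORS,
    Grouping.TIME_SERIES,
    Grouping.OTHER,
)


def get_category(name: str) -> CategorySpec:
    """Look up a registered category or raise ``KeyError``."""
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown metadata category: {name!r}") from None
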