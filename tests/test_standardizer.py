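"""The three-pass pipeline: passes, guarantee, idempotence, determinism."""

import copy
import random

import pytest

from samplemeta.categories import ValueClass, get_category
from samplemeta.errors import (
    MatrixValidationError,
    ModelVersionMismatch,
    OrthogonalityError,
)
from samplemeta.fixtures import FixtureConfig, generate_matrix, generate_store
from samplemeta.matrix_io import SubmissionMatrix
from samplemeta.standardizer import (
    ConfirmationRequired,
    ConfirmationSet,
    auto_confirm,
    classify_cell,
    fit_models,
    standardize,
    verify_guarantee,
)
from samplemeta.vocabulary import validate_store


def _matrix(store, categories, rows):
    return SubmissionMatrix(
        categories=[get_category(c) for c in categories], rows=rows
    )


@pytest.mark.parametrize(
    "name,expected",
    [
        ("species", ValueClass.CONTROLLED),
        ("drugDoseMagnitude", ValueClass.NUMERIC),
        ("comment", ValueClass.FREETEXT),
        ("sampleLabel", ValueClass.FREETEXT),
    ],
)
def test_classify_cell(name, expected):
    assert classify_cell(get_category(name)) is expected


class TestPassOne:
    def test_synonym_numeric_and_empty_cells(self, store):
        matrix = _matrix(
            store,
            ["sampleLabel", "species", "age", "ageUnit"],
            [["s1", "mouse", "10", "weeks"], ["s2", "", "", ""]],
        )
        result = standardize(matrix, store)
        assert result.matrix.rows[0] == ["s1", "mus musculus", "10", "week"]
        assert result.matrix.rows[1] == ["s2", "", "", ""]
        passes = {(e.category, e.row): e.pass_ for e in result.report.entries}
        assert passes[("species", 0)] == "synonym"
        assert passes[("age", 0)] == "passthrough"
        assert passes[("species", 1)] == "empty"

    def test_close_typo_is_auto_matched(self, store):
        matrix = _matrix(
            store, ["sampleLabel", "species"], [["s1", "mus musculos"]]
        )
        result = standardize(matrix, store)
        entry = result.report.entries[-1]
        assert entry.pass_ == "nn_auto"
        assert entry.final == "mus musculus"
        assert entry.similarity > 0.8

    @pytest.mark.parametrize("bad", ["ten", "1,5", "1.5e", "12 mg"])
    def test_unparseable_numeric_cell_raises(self, store, bad):
        matrix = _matrix(store, ["sampleLabel", "age"], [["s1", bad]])
        with pytest.raises(MatrixValidationError, match="not a number"):
            standardize(matrix, store)

    @pytest.mark.parametrize("ok", ["10", "-3.5", ".5", "1e-3", "2.5E4"])
    def test_decimal_and_scientific_numbers_accepted(self, store, ok):
        matrix = _matrix(store, ["sampleLabel", "age"], [["s1", ok]])
        standardize(matrix, store)

    def test_stale_models_are_refused(self, store):
        models = fit_models(store)
        store.add_main_term("species", "canis lupus")
        matrix = _matrix(store, ["sampleLabel", "species"], [["s1", "mouse"]])
        with pytest.raises(ModelVersionMismatch):
            standardize(matrix, store, models)


class TestPassTwoAndThree:
    def test_substring_becomes_proposal_never_auto(self, store):
        matrix = _matrix(store, ["sampleLabel", "species"], [["s1", "norvegicus"]])
        with pytest.raises(ConfirmationRequired) as exc:
            standardize(matrix, store)
        proposals = exc.value.pending[0].proposals
        assert any(p.term == "rattus norvegicus" for p in proposals)

    def test_substring_rescues_queries_the_vector_pass_cannot(self, store):
        # "us" is shorter than a trigram, so the first pass sees a zero
        # vector; only the substring pass can propose anything
        matrix = _matrix(store, ["sampleLabel", "species"], [["s1", "us"]])
        with pytest.raises(ConfirmationRequired) as exc:
            standardize(matrix, store)
        proposals = exc.value.pending[0].proposals
        assert proposals and all(p.source == "substring" for p in proposals)
        assert {"mus musculus", "rattus norvegicus"} <= {p.term for p in proposals}

    def test_confirmed_substring_proposal_resolves(self, store):
        matrix = _matrix(store, ["sampleLabel", "species"], [["s1", "norvegicus"]])
        confirmations = ConfirmationSet(
            accepted_proposals={("species", "norvegicus"): "rattus norvegicus"}
        )
        result = standardize(matrix, store, confirmations=confirmations)
        entry = result.report.entries[-1]
        assert entry.final == "rattus norvegicus"
        assert entry.pass_ in ("substring", "nn_confirmed")
        assert result.report.new_terms == []

    def test_new_term_is_added_and_reported(self, store):
        matrix = _matrix(store, ["sampleLabel", "drugName"], [["s1", "Ozone"]])
        confirmations = ConfirmationSet(
            accepted_new_terms={("drugName", "ozone"): "ozone"}
        )
        result = standardize(matrix, store, confirmations=confirmations)
        assert result.report.new_terms == [("drugName", "ozone")]
        assert "ozone" in result.store["drugName"].main_terms
        assert "ozone" not in store["drugName"].main_terms  # caller untouched
        assert result.models["drugName"].vocab_versions["drugName"] == (
            result.store["drugName"].version
        )

    def test_new_term_clashing_with_other_category_raises(self, store):
        matrix = _matrix(store, ["sampleLabel", "drugName"], [["s1", "housemouse"]])
        confirmations = ConfirmationSet(
            accepted_new_terms={("drugName", "housemouse"): "mus musculus"}
        )
        with pytest.raises(OrthogonalityError, match="species"):
            standardize(matrix, store, confirmations=confirmations)

    def test_missing_confirmation_enumerates_values(self, store):
        matrix = _matrix(
            store,
            ["sampleLabel", "drugName"],
            [["s1", "ozone"], ["s2", "helium"]],
        )
        with pytest.raises(ConfirmationRequired) as exc:
            standardize(matrix, store)
        originals = {p.original for p in exc.value.pending}
        assert originals == {"ozone", "helium"}

    def test_confirmation_maps_must_be_disjoint(self):
        with pytest.raises(ValueError):
            ConfirmationSet(
                accepted_proposals={("species", "x"): "mus musculus"},
                accepted_new_terms={("species", "x"): "x"},
            )


class TestStandardizeWhole:
    def test_worked_example_standardizes_exactly(self, example):
        result = standardize(
            example.matrix, example.store, confirmations=example.confirmations
        )
        assert result.matrix.rows == example.expected_matrix.rows
        assert set(result.report.new_terms) == example.expected_new_terms
        assert verify_guarantee(result.matrix, result.store) == []

    def test_multi_value_cells_curated_independently(self, store):
        matrix = _matrix(
            store, ["sampleLabel", "species"], [["s1", "mouse; human"]]
        )
        result = standardize(matrix, store)
        assert result.matrix.rows[0][1] == "mus musculus;homo sapiens"
        species_entries = [
            e for e in result.report.entries if e.category == "species"
        ]
        assert [e.value_index for e in species_entries] == [0, 1]

    def test_freetext_cells_are_not_split(self, store):
        matrix = _matrix(
            store,
            ["sampleLabel", "species", "comment"],
            [["s1", "mouse", "high dose; recheck"]],
        )
        result = standardize(matrix, store)
        assert result.matrix.rows[0][2] == "high dose; recheck"

    def test_already_standardized_matrix_is_fixed_point(self, example):
        first = standardize(
            example.matrix, example.store, confirmations=example.confirmations
        )
        second = standardize(first.matrix, first.store)
        assert second.matrix.rows == first.matrix.rows
        controlled = [
            e
            for e in second.report.entries
            if get_category(e.category).is_controlled and e.pass_ != "empty"
        ]
        assert controlled and all(e.pass_ == "exact" for e in controlled)
        assert second.report.new_terms == []
        assert second.store.versions() == first.store.versions()

    def test_identical_inputs_give_identical_outputs(self, example):
        a = standardize(
            example.matrix, example.store, confirmations=example.confirmations
        )
        b = standardize(
            example.matrix, example.store, confirmations=example.confirmations
        )
        assert a.matrix.rows == b.matrix.rows
        assert a.report.to_dict() == b.report.to_dict()


class TestGuaranteeProperty:
    """Adopting every unresolved value must always land in the vocabulary."""

    @pytest.mark.parametrize("seed", range(12))
    def test_guarantee_and_idempotence_on_generated_matrices(self, seed):
        config = FixtureConfig(seed=seed, n_terms=20, synonym_rate=0.4)
        store = generate_store(["species", "organ", "drugName"], config)
        rng = random.Random(seed + 1000)
        matrix = generate_matrix(store, n_rows=8, config=config, rng=rng)
        snapshot = copy.deepcopy(store)
        try:
            result = standardize(matrix, store)
        except ConfirmationRequired as exc:
            confirmations = auto_confirm(exc.pending)
            result = standardize(matrix, store, confirmations=confirmations)
        # guarantee: every non-empty controlled value is a main term
        assert verify_guarantee(result.matrix, result.store) == []
        assert validate_store(result.store) == []
        # all-or-nothing: the caller's store was never touched
        assert store.versions() == snapshot.versions()
        # report completeness: one entry per delimited value or empty cell
        expected_entries = 0
        for row in matrix.rows:
            for j, spec in enumerate(matrix.categories):
                if not row[j].strip() or not spec.is_controlled:
                    expected_entries += 1
                else:
                    expected_entries += len(row[j].split(";"))
        assert len(result.report.entries) == expected_entries
        # idempotence: a second run is the identity, exact everywhere
        second = standardize(result.matrix, result.store, result.models)
        assert second.matrix.rows == result.matrix.rows
        assert second.report.new_terms == []
        controlled = [
            e
            for e in second.report.entries
            if get_category(e.category).is_controlled and e.pass_ != "empty"
        ]
        assert all(e.pass_ == "exact" for e in controlled)
        assert second.store.versions() == result.store.versions()
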