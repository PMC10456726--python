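"""Ontology ingestion: dialect readers, subtree extraction, exclusions."""

import itertools
import random

import pytest

from samplemeta.categories import get_category
from samplemeta.errors import OntologyParseError
from samplemeta.fixtures import organ_heading_fixture, species_rule_fixture
from samplemeta.ontology import (
    DropRank,
    DropRankNameContains,
    DropRankNameWithDigits,
    DropSubtreeNameContains,
    ExtractionSpec,
    OntologyGraph,
    OntologyNode,
    SubtractReference,
    apply_exclusions,
    build_vocabulary,
    load_taxdump_dialect,
    load_treenumber_dialect,
    subtract_reference,
    subtree_nodes,
    subtree_terms,
)
from samplemeta.vocabulary import validate_store, VocabularyStore


@pytest.fixture()
def taxdump_paths(tmp_path, species_fixture):
    return species_fixture.write(tmp_path)


class TestTaxdumpDialect:
    def test_chain_parses_with_names_and_synonyms(self, taxdump_paths):
        graph = load_taxdump_dialect(*taxdump_paths)
        assert len(graph) == 19
        mouse = next(n for n in graph.nodes.values() if n.name == "mus musculus")
        assert set(mouse.synonyms) == {"mouse", "mice", "house mouse"}
        assert mouse.rank == "species"

    def test_dangling_parent_raises(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text("1\t|\t99\t|\tno rank\t|\n")
        (tmp_path / "names.dmp").write_text("1\t|\troot\t|\t\t|\tscientific name\t|\n")
        with pytest.raises(OntologyParseError, match="dangling parent"):
            load_taxdump_dialect(tmp_path / "nodes.dmp", tmp_path / "names.dmp")

    def test_duplicate_scientific_name_raises(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text("1\t|\t1\t|\tno rank\t|\n")
        (tmp_path / "names.dmp").write_text(
            "1\t|\troot\t|\t\t|\tscientific name\t|\n"
            "1\t|\tother\t|\t\t|\tscientific name\t|\n"
        )
        with pytest.raises(OntologyParseError, match="duplicate scientific name"):
            load_taxdump_dialect(tmp_path / "nodes.dmp", tmp_path / "names.dmp")

    def test_cycle_raises(self, tmp_path):
        (tmp_path / "nodes.dmp").write_text(
            "1\t|\t2\t|\tno rank\t|\n2\t|\t1\t|\tno rank\t|\n"
        )
        (tmp_path / "names.dmp").write_text(
            "1\t|\ta\t|\t\t|\tscientific name\t|\n"
            "2\t|\tb\t|\t\t|\tscientific name\t|\n"
        )
        with pytest.raises(OntologyParseError, match="cycle"):
            load_taxdump_dialect(tmp_path / "nodes.dmp", tmp_path / "names.dmp")


class TestTreenumberDialect:
    def test_prefix_parentage_and_multi_parent(self, tmp_path):
        path = tmp_path / "organ.tsv"
        path.write_text(organ_heading_fixture())
        graph = load_treenumber_dialect(path)
        by_name = {n.name: n.id for n in graph.nodes.values()}
        # A01.456 is under A01; A01 is not under A (dot-segment rule keeps
        # the bare letter a separate node with no children here)
        assert by_name["body regions"] in graph.parents(by_name["head"])
        mouth_parents = graph.parents(by_name["mouth"])
        assert by_name["head"] in mouth_parents
        assert by_name["digestive system"] in mouth_parents
        assert len(mouth_parents) == 2

    def test_segment_semantics_not_raw_prefix(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("a\tA01\t\nb\tA011\t\nc\tA01.1\t\n")
        graph = load_treenumber_dialect(path)
        by_name = {n.name: n.id for n in graph.nodes.values()}
        assert graph.parents(by_name["b"]) == set()  # A01 not a parent of A011
        assert graph.parents(by_name["c"]) == {by_name["a"]}

    def test_malformed_heading_raises(self, tmp_path):
        path = tmp_path / "x.tsv"
        path.write_text("a\tA01..2\t\n")
        with pytest.raises(OntologyParseError, match="malformed heading"):
            load_treenumber_dialect(path)

    def test_empty_file_gives_empty_graph(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert len(load_treenumber_dialect(path)) == 0


def _chain_graph():
    g = OntologyGraph(
        [
            OntologyNode("r", "root"),
            OntologyNode("a", "left leaf"),
            OntologyNode("b", "right leaf"),
        ]
    )
    g.add_edge("r", "a")
    g.add_edge("r", "b")
    return g


class TestSubtree:
    def test_root_with_two_leaves(self):
        assert subtree_terms(_chain_graph(), ["r"]) == {
            "root",
            "left leaf",
            "right leaf",
        }

    def test_diamond_counted_once(self):
        g = OntologyGraph(
            [OntologyNode(i, f"n{i}") for i in ["r1", "r2", "x"]]
        )
        g.add_edge("r1", "x")
        g.add_edge("r2", "x")
        assert subtree_nodes(g, ["r1", "r2"]) == {"r1", "r2", "x"}

    def test_unknown_root_raises(self):
        with pytest.raises(ValueError, match="unknown root"):
            subtree_nodes(_chain_graph(), ["nope"])

    def test_heading_roots_select_lower_headings(self, tmp_path):
        path = tmp_path / "organ.tsv"
        path.write_text(organ_heading_fixture())
        graph = load_treenumber_dialect(path)
        assert subtree_terms(graph, ["A"]) == {
            "anatomical entity",
            "body regions",
            "head",
            "respiratory system",
            "lung",
            "digestive system",
            "mouth",
        }
        assert subtree_terms(graph, ["A01"]) == {"body regions", "head", "mouth"}

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_closure_on_random_dags(self, seed):
        rng = random.Random(seed)
        n = rng.randint(20, 200)
        g = OntologyGraph([OntologyNode(str(i), f"node {i}") for i in range(n)])
        edges = set()
        for child in range(1, n):
            for parent in rng.sample(range(child), min(child, rng.randint(1, 2))):
                edges.add((str(parent), str(child)))
                g.add_edge(str(parent), str(child))
        roots = [str(i) for i in rng.sample(range(n), rng.randint(1, 5))]
        # independent oracle: iterate edge expansion to a fixed point
        reach = set(roots)
        changed = True
        while changed:
            changed = False
            for p, c in edges:
                if p in reach and c not in reach:
                    reach.add(c)
                    changed = True
        assert subtree_nodes(g, roots) == reach


class TestExclusions:
    def test_each_rule_drops_its_target(self, taxdump_paths, species_fixture):
        graph = load_taxdump_dialect(*taxdump_paths)
        names = lambda ids: {graph.nodes[i].name for i in ids}
        everything = subtree_nodes(graph, ["1"])
        assert "balb/c" not in names(
            apply_exclusions(everything, graph, [DropRank("strain")])
        )
        env = apply_exclusions(
            everything, graph, [DropSubtreeNameContains("environmental sample")]
        )
        assert {"environmental samples", "uncultured eukaryote"} & names(env) == set()
        assert "rna/dna sample group" not in names(
            apply_exclusions(everything, graph, [DropRankNameContains("no rank", "/")])
        )
        assert "influenza a virus 1918" not in names(
            apply_exclusions(everything, graph, [DropRankNameWithDigits("species")])
        )
        assert "cloning vector lambda" not in names(
            apply_exclusions(
                everything, graph, [DropRankNameContains("species", "vector")]
            )
        )

    def test_full_rule_set_yields_recorded_survivors(
        self, taxdump_paths, species_fixture
    ):
        graph = load_taxdump_dialect(*taxdump_paths)
        survivors = apply_exclusions(
            subtree_nodes(graph, species_fixture.spec.include_roots),
            graph,
            species_fixture.spec.exclusions,
        )
        assert {
            graph.nodes[i].name for i in survivors
        } == species_fixture.expected_survivors

    def test_rules_commute(self, taxdump_paths, species_fixture):
        graph = load_taxdump_dialect(*taxdump_paths)
        everything = subtree_nodes(graph, ["1"])
        rules = list(species_fixture.spec.exclusions)
        reference = apply_exclusions(everything, graph, rules)
        rng = random.Random(0)
        for _ in range(10):
            rng.shuffle(rules)
            assert apply_exclusions(everything, graph, rules) == reference

    def test_rules_on_absent_ranks_are_vacuous(self):
        g = _chain_graph()
        everything = subtree_nodes(g, ["r"])
        assert apply_exclusions(everything, g, [DropRank("strain")]) == everything

    @pytest.mark.parametrize(
        "terms,reference,expected",
        [
            ({"balb/c", "homo sapiens"}, {"homo sapiens"}, {"balb/c"}),
            ({"a", "b"}, {"c"}, {"a", "b"}),
            ({"a"}, {"a", "b"}, set()),
        ],
    )
    def test_subtract_reference(self, terms, reference, expected):
        assert subtract_reference(terms, reference) == expected


class TestBuildVocabulary:
    def test_species_fixture_builds_expected_vocabulary(
        self, taxdump_paths, species_fixture
    ):
        graph = load_taxdump_dialect(*taxdump_paths)
        vocab = build_vocabulary(graph, species_fixture.spec, get_category("species"))
        assert vocab.main_terms == set(species_fixture.expected_survivors)
        assert vocab.synonym_map["mouse"] == "mus musculus"
        assert vocab.synonym_map["zebrafish"] == "danio rerio"
        store = VocabularyStore([vocab])
        assert validate_store(store) == []

    def test_no_exclusions_keeps_all_names(self):
        vocab = build_vocabulary(
            _chain_graph(), ExtractionSpec(include_roots=("r",)), get_category("organ")
        )
        assert vocab.main_terms == {"root", "left leaf", "right leaf"}

    def test_duplicate_names_collapse_to_one_main_term(self):
        g = OntologyGraph(
            [
                OntologyNode("r", "root"),
                OntologyNode("a", "Shared Name"),
                OntologyNode("b", "shared  name"),
            ]
        )
        g.add_edge("r", "a")
        g.add_edge("r", "b")
        vocab = build_vocabulary(
            g, ExtractionSpec(include_roots=("r",)), get_category("organ")
        )
        assert vocab.main_terms == {"root", "shared name"}

    def test_synonym_colliding_with_main_term_is_dropped(self):
        g = OntologyGraph(
            [
                OntologyNode("r", "root"),
                OntologyNode("a", "lung", synonyms=["pulmo", "liver"]),
                OntologyNode("b", "liver"),
            ]
        )
        g.add_edge("r", "a")
        g.add_edge("r", "b")
        vocab = build_vocabulary(
            g, ExtractionSpec(include_roots=("r",)), get_category("organ")
        )
        assert vocab.synonym_map == {"pulmo": "lung"}

    def test_subtract_reference_rule_enforces_orthogonality(self, taxdump_paths):
        graph = load_taxdump_dialect(*taxdump_paths)
        spec = ExtractionSpec(
            include_roots=("1",),
            exclusions=(SubtractReference(frozenset({"mus musculus"})),),
        )
        vocab = build_vocabulary(graph, spec, get_category("strain"))
        assert "mus musculus" not in vocab.main_terms
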