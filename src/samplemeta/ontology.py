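"""Build controlled vocabularies from ontology dumps.

Two dump dialects are supported, covering the two shapes that the
large public biomedical ontologies come in:

* the *taxdump* dialect — pipe-delimited node and name tables as used
  by ranked taxonomies (node id, parent id, rank; names carry a name
  class, where the scientific name becomes the node name and every
  other class becomes a synonym);
* the *tree-number* dialect — a TSV of descriptor terms with
  dot-separated tree numbers (``A01.111`` sits under ``A01``) and
  optional synonym lists, as used by heading-organised thesauri.

Vocabulary construction is subtree extraction (every node at or below
a set of roots) followed by a closed set of exclusion rules — drop a
rank, drop whole subtrees under nodes whose name contains a substring,
drop rank-restricted name patterns, and subtract a reference term set
(which is how orthogonality between overlapping sources is enforced
at build time).  Rules are conjunctive, so their order never matters.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .categories import CategorySpec
from .errors import OntologyParseError
from .vocabulary import Vocabulary, normalize_string

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyNode",
    "OntologyGraph",
    "ExtractionSpec",
    "load_taxdump_dialect",
    "load_treenumber_dialect",
    "subtree_nodes",
    "subtree_terms",
    "apply_exclusions",
    "subtract_reference",
    "build_vocabulary",
    "DropRank",
    "DropSubtreeNameContains",
    "DropRankNameContains",
    "DropRankNameWithDigits",
    "SubtractReference",
]


@dataclass
class OntologyNode:
    id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    rank: str | None = None
    headings: tuple[str, ...] = ()


class OntologyGraph:
    """A rooted, acyclic ontology; nodes may have multiple parents.

    Edges in the underlying digraph run parent -> child, so descendant
    queries are reachability queries.
    """

    def __init__(self, nodes: Iterable[OntologyNode] = ()):
        self.nodes: dict[str, OntologyNode] = {}
        self._graph = nx.DiGraph()
        for node in nodes:
            self.add_node(node)

    def add_node(self, node: OntologyNode) -> None:
        if node.id in self.nodes:
            raise OntologyParseError(f"duplicate node id {node.id!r}")
        self.nodes[node.id] = node
        self._graph.add_node(node.id)

    def add_edge(self, parent: str, child: str) -> None:
        if parent not in self.nodes:
            raise OntologyParseError(
                f"node {child!r} references missing parent {parent!r}"
            )
        self._graph.add_edge(parent, child)

    def parents(self, node_id: str) -> set[str]:
        return set(self._graph.predecessors(node_id))

    def descendants(self, node_id: str) -> set[str]:
        return nx.descendants(self._graph, node_id)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise OntologyParseError(f"ontology contains a cycle: {cycle}")

    def __len__(self) -> int:
        return len(self.nodes)


# -- dialect readers -------------------------------------------------


def _split_pipe_row(line: str) -> list[str]:
    # taxdump rows are "field\t|\tfield\t|\t...\t|" — split on the pipe
    # and strip surrounding tabs/spaces from each field
    parts = line.rstrip("\n").split("|")
    return [p.strip(" \t") for p in parts]


def load_taxdump_dialect(nodes_path: str | Path, names_path: str | Path) -> OntologyGraph:
    """Read a ranked-taxonomy dump (pipe-delimited node and name tables).

    The node table carries ``id | parent id | rank``; the name table
    carries ``id | name | unique name | name class``.  The row whose
    name class is ``scientific name`` provides the node name (at most
    one per id); rows of any other class are stored as synonyms.  A
    node whose parent is itself is treated as the root.
    """
    graph = OntologyGraph()
    parent_of: dict[str, str] = {}
    with open(nodes_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_pipe_row(line)
            if len(fields) < 3:
                raise OntologyParseError(
                    f"{nodes_path}: line {lineno}: expected at least 3 fields"
                )
            node_id, parent_id, rank = fields[0], fields[1], fields[2]
            graph.add_node(OntologyNode(id=node_id, name="", rank=rank))
            parent_of[node_id] = parent_id
    with open(names_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = _split_pipe_row(line)
            if len(fields) < 4:
                raise OntologyParseError(
                    f"{names_path}: line {lineno}: expected at least 4 fields"
                )
            node_id, name, _unique, name_class = fields[:4]
            if node_id not in graph.nodes:
                raise OntologyParseError(
                    f"{names_path}: line {lineno}: name for unknown node {node_id!r}"
                )
            node = graph.nodes[node_id]
            if name_class == "scientific name":
                if node.name:
                    raise OntologyParseError(
                        f"{names_path}: line {lineno}: duplicate scientific name "
                        f"for node {node_id!r}"
                    )
                node.name = name
            else:
                node.synonyms.append(name)
    for node_id, parent_id in parent_of.items():
        if parent_id == node_id:
            continue  # self-parent marks the root
        if parent_id not in graph.nodes:
            raise OntologyParseError(
                f"node {node_id!r} has dangling parent {parent_id!r}"
            )
        graph.add_edge(parent_id, node_id)
    for node in graph.nodes.values():
        if not node.name:
            raise OntologyParseError(f"node {node.id!r} has no scientific name")
    graph.validate()
    return graph


_HEADING_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*(\.[A-Za-z0-9]+)*$")


def load_treenumber_dialect(path: str | Path) -> OntologyGraph:
    """Read a heading-organised descriptor TSV.

    Columns: term, semicolon-joined tree numbers, semicolon-joined
    synonyms (optional).  Parentage is inferred from tree numbers by
    dropping the last dot-separated segment: ``A01.111`` is a child of
    whichever term owns heading ``A01``.  Segment semantics mean
    ``A01`` is *not* a parent of ``A011``.  A term with k headings has
    up to k parents.
    """
    graph = OntologyGraph()
    heading_owner: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise OntologyParseError(
                    f"{path}: line {lineno}: expected term and headings columns"
                )
            term = fields[0].strip()
            headings = tuple(h.strip() for h in fields[1].split(";") if h.strip())
            synonyms = []
            if len(fields) > 2 and fields[2].strip():
                synonyms = [s.strip() for s in fields[2].split(";") if s.strip()]
            if not term:
                raise OntologyParseError(f"{path}: line {lineno}: empty term")
            if not headings:
                raise OntologyParseError(f"{path}: line {lineno}: no headings")
            for heading in headings:
                if not _HEADING_RE.match(heading):
                    raise OntologyParseError(
                        f"{path}: line {lineno}: malformed heading {heading!r}"
                    )
            node_id = f"line{lineno}"
            graph.add_node(
                OntologyNode(id=node_id, name=term, synonyms=synonyms, headings=headings)
            )
            for heading in headings:
                if heading in heading_owner:
                    raise OntologyParseError(
                        f"{path}: line {lineno}: heading {heading!r} already "
                        f"assigned to another term"
                    )
                heading_owner[heading] = node_id
    for node in graph.nodes.values():
        for heading in node.headings:
            if "." not in heading:
                continue
            parent_heading = heading.rsplit(".", 1)[0]
            parent_id = heading_owner.get(parent_heading)
            if parent_id is not None and parent_id != node.id:
                graph.add_edge(parent_id, node.id)
    graph.validate()
    return graph


# -- subtree extraction ----------------------------------------------


def _heading_matches(heading: str, root: str) -> bool:
    """True if ``heading`` lies at or below the tree-number ``root``.

    Matches the heading itself, any heading extending the root by dot
    segments, and — for a purely alphabetic root such as ``A`` — any
    heading whose first segment starts with that letter prefix
    followed by digits (``A01.111`` under ``A``).
    """
    if heading == root or heading.startswith(root + "."):
        return True
    if root.isalpha():
        first = heading.split(".", 1)[0]
        return first.startswith(root) and first[len(root) :].isdigit()
    return False


def _resolve_roots(graph: OntologyGraph, roots: Sequence[str]) -> set[str]:
    resolved: set[str] = set()
    for root in roots:
        if root in graph.nodes:
            resolved.add(root)
            continue
        matched = {
            node.id
            for node in graph.nodes.values()
            if any(_heading_matches(h, root) for h in node.headings)
        }
        if not matched:
            raise ValueError(f"unknown root {root!r} (no node id or heading match)")
        resolved |= matched
    return resolved


def subtree_nodes(graph: OntologyGraph, roots: Sequence[str]) -> set[str]:
    """Ids of every node that is a root or a descendant of a root."""
    included = _resolve_roots(graph, roots)
    result = set(included)
    for root in included:
        result |= graph.descendants(root)
    return result


def subtree_terms(graph: OntologyGraph, roots: Sequence[str]) -> set[str]:
    """Names of the nodes selected by :func:`subtree_nodes` (set semantics)."""
    return {graph.nodes[i].name for i in subtree_nodes(graph, roots)}


# -- exclusion rules -------------------------------------------------


@dataclass(frozen=True)
class DropRank:
    """Drop every node of the given rank."""

    rank: str

    def drop_set(self, graph: OntologyGraph) -> set[str]:
        return {i for i, n in graph.nodes.items() if n.rank == self.rank}


@dataclass(frozen=True)
class DropSubtreeNameContains:
    """Drop nodes whose name contains a substring, with their whole subtree.

    Matching is case-insensitive on normalized names; the matching node
    itself is dropped along with all of its descendants.
    """

    substring: str

    def drop_set(self, graph: OntologyGraph) -> set[str]:
        needle = normalize_string(self.substring)
        dropped: set[str] = set()
        for node_id, node in graph.nodes.items():
            if needle in normalize_string(node.name):
                dropped.add(node_id)
                dropped |= graph.descendants(node_id)
        return dropped


@dataclass(frozen=True)
class DropRankNameContains:
    """Drop nodes of a given rank whose name contains a substring."""

    rank: str
    substring: str

    def drop_set(self, graph: OntologyGraph) -> set[str]:
        needle = normalize_string(self.substring)
        return {
            i
            for i, n in graph.nodes.items()
            if n.rank == self.rank and needle in normalize_string(n.name)
        }


@dataclass(frozen=True)
class DropRankNameWithDigits:
    """Drop nodes of a given rank whose name contains any digit."""

    rank: str

    def drop_set(self, graph: OntologyGraph) -> set[str]:
        return {
            i
            for i, n in graph.nodes.items()
            if n.rank == self.rank and any(c.isdigit() for c in n.name)
        }


@dataclass(frozen=True)
class SubtractReference:
    """Remove nodes whose normalized name is in a reference term set.

    This is the build-time orthogonality mechanism: a vocabulary built
    after another subtracts the earlier one's main terms.
    """

    reference: frozenset[str]

    def drop_set(self, graph: OntologyGraph) -> set[str]:
        return {
            i
            for i, n in graph.nodes.items()
            if normalize_string(n.name) in self.reference
        }


ExclusionRule = (
    DropRank
    | DropSubtreeNameContains
    | DropRankNameContains
    | DropRankNameWithDigits
    | SubtractReference
)

_RULE_NAMES = {
    "drop_rank": DropRank,
    "drop_descendants_of_name_containing": DropSubtreeNameContains,
    "drop_rank_name_containing": DropRankNameContains,
    "drop_rank_name_matching_digits": DropRankNameWithDigits,
    "subtract_reference": SubtractReference,
}


def rule_from_dict(entry: dict) -> ExclusionRule:
    """Build an exclusion rule from its JSON form (``{"rule": ..., ...}``)."""
    entry = dict(entry)
    name = entry.pop("rule")
    try:
        cls = _RULE_NAMES[name]
    except KeyError:
        raise ValueError(f"unknown exclusion rule {name!r}") from None
    if cls is DropRank:
        return DropRank(rank=entry["rank"])
    if cls is DropSubtreeNameContains:
        return DropSubtreeNameContains(substring=entry["substring"])
    if cls is DropRankNameContains:
        return DropRankNameContains(rank=entry["rank"], substring=entry["substring"])
    if cls is DropRankNameWithDigits:
        return DropRankNameWithDigits(rank=entry["rank"])
    return SubtractReference(
        reference=frozenset(normalize_string(t) for t in entry["reference"])
    )


@dataclass(frozen=True)
class ExtractionSpec:
    """Roots plus exclusion rules defining one vocabulary's extraction."""

    include_roots: tuple[str, ...]
    exclusions: tuple[ExclusionRule, ...] = ()

    @classmethod
    def from_dict(cls, data: dict) -> "ExtractionSpec":
        return cls(
            include_roots=tuple(data["include_roots"]),
            exclusions=tuple(rule_from_dict(e) for e in data.get("exclusions", [])),
        )


def apply_exclusions(
    candidates: set[str],
    graph: OntologyGraph,
    exclusions: Sequence[ExclusionRule],
) -> set[str]:
    """Apply every exclusion rule conjunctively to a candidate node set.

    Each rule contributes a drop set computed from the full graph, so
    the result is invariant under permutation of the rule list.  Rules
    referring to ranks or names absent from the graph are vacuous.
    """
    dropped: set[str] = set()
    for rule in exclusions:
        dropped |= rule.drop_set(graph)
    return candidates - dropped


def subtract_reference(terms: set[str], reference: set[str]) -> set[str]:
    """Set-difference on normalized term sets."""
    return {t for t in terms if normalize_string(t) not in reference}


def build_vocabulary(
    graph: OntologyGraph, spec: ExtractionSpec, category: CategorySpec
) -> Vocabulary:
    """Extract, filter and package one category's vocabulary.

    Main terms are the normalized, deduplicated names of the surviving
    subtree nodes; node synonyms become synonym entries unless they
    collide with a main term of the same vocabulary, in which case the
    synonym is dropped (and logged) — main terms are the identity
    anchors.  A synonym claimed for two different main terms keeps the
    first assignment in deterministic (sorted main term) order.
    """
    candidates = subtree_nodes(graph, spec.include_roots)
    surviving = apply_exclusions(candidates, graph, spec.exclusions)
    main_terms: set[str] = set()
    synonyms_by_node: list[tuple[str, list[str]]] = []
    for node_id in sorted(surviving):
        node = graph.nodes[node_id]
        name = normalize_string(node.name)
        if not name:
            continue
        main_terms.add(name)
        synonyms_by_node.append((name, node.synonyms))
    synonym_map: dict[str, str] = {}
    for main, synonyms in sorted(synonyms_by_node):
        for raw in synonyms:
            syn = normalize_string(raw)
            if not syn:
                continue
            if syn in main_terms:
                logger.debug(
                    "dropping synonym %r of %r: collides with a main term", syn, main
                )
                continue
            if syn in synonym_map and synonym_map[syn] != main:
                logger.debug(
                    "synonym %r already maps to %r; ignoring mapping to %r",
                    syn,
                    synonym_map[syn],
                    main,
                )
                continue
            synonym_map[syn] = main
    return Vocabulary(category=category, main_terms=main_terms, synonym_map=synonym_map)
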