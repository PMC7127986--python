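"""Disease normalization against a cancer-slim ontology.

Disease terms arrive as labels, synonyms ("CLL") or source-internal shorthand
("L" for lung cancer). They are matched to ontology identifiers and grouped
to high-level "TopNode" terms — a designated slim of cancer types (breast
cancer, lung cancer, ...) used to compare a patient's diagnosis with the
disease scope of an interpretation.

The ontology is a DAG of is-a edges (child -> parent). It can be loaded from
a JSON node/edge-list file or an OBO file (via obonet); both become the same
:class:`OntologyGraph` backed by networkx.
"""

from __future__ import annotations

import functools
import json
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx

from .model import CANCER_ROOT, DiseaseMappingStatus, DiseaseNorm


class UnknownTermError(KeyError):
    """Ontology identifier not present in the graph."""


@dataclass
class OntologyGraph:
    """Is-a DAG with labels, synonyms and a designated TopNode slim."""

    graph: nx.DiGraph  # directed child -> parent
    labels: dict[str, str]
    synonyms: dict[str, set[str]] = field(default_factory=dict)  # lower -> ids
    topnode_set: set[str] = field(default_factory=set)
    root_cancer: str = CANCER_ROOT

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("ontology is-a graph must be acyclic")
        self._label_index = {}
        for doid, label in self.labels.items():
            self._label_index.setdefault(label.strip().lower(), set()).add(doid)

    def __contains__(self, doid: str) -> bool:
        return doid in self.graph

    def ancestors_or_self(self, doid: str) -> set[str]:
        """All is-a ancestors of ``doid`` including itself."""
        if doid not in self.graph:
            raise UnknownTermError(doid)
        return nx.descendants(self.graph, doid) | {doid}

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        return ancestor in self.ancestors_or_self(descendant)

    def lookup_label(self, term: str) -> set[str]:
        return set(self._label_index.get(term.strip().lower(), set()))

    def lookup_synonym(self, term: str) -> set[str]:
        return set(self.synonyms.get(term.strip().lower(), set()))

    # -- construction -------------------------------------------------------

    @classmethod
    def from_json(cls, path) -> "OntologyGraph":
        """Load from a JSON file with ``nodes``, ``edges`` and ``topnodes``."""
        with open(path) as fh:
            data = json.load(fh)
        g = nx.DiGraph()
        labels, synonyms = {}, {}
        for node in data["nodes"]:
            g.add_node(node["id"])
            labels[node["id"]] = node.get("label", "")
            for syn in node.get("synonyms", []):
                synonyms.setdefault(syn.strip().lower(), set()).add(node["id"])
        for child, parent in data["edges"]:
            g.add_edge(child, parent)
        return cls(g, labels, synonyms, set(data.get("topnodes", [])))

    @classmethod
    def from_obo(cls, path, topnodes: set[str] = frozenset()) -> "OntologyGraph":
        """Load an OBO 1.4 file; ``is_a`` edges become child -> parent."""
        import obonet

        multigraph = obonet.read_obo(path)
        g = nx.DiGraph()
        labels, synonyms = {}, {}
        for node, attrs in multigraph.nodes(data=True):
            g.add_node(node)
            labels[node] = attrs.get("name", "")
            for syn in attrs.get("synonym", []):
                # obonet keeps the quoted OBO syntax: "text" SCOPE [...]
                text = syn.split('"')[1] if '"' in syn else syn
                synonyms.setdefault(text.strip().lower(), set()).add(node)
        for child, parent, key in multigraph.edges(keys=True):
            if key == "is_a":
                g.add_edge(child, parent)
        return cls(g, labels, synonyms, set(topnodes))


def normalize_disease(
    term: str,
    graph: OntologyGraph,
    shorthand: Optional[dict[str, str]] = None,
) -> DiseaseNorm:
    """Map a free-text disease term to an ontology identifier.

    Lookup order: exact label match, then synonym match (both
    case-insensitive, whitespace-trimmed), then the per-source shorthand
    table. A term matching several identifiers at the same stage is left
    unmapped with ``needs_review`` set, and a total miss is simply unmapped;
    failures are encoded in the status, never raised.
    """
    cleaned = (term or "").strip()
    if not cleaned:
        return DiseaseNorm(label=term or "")
    for hits in (graph.lookup_label(cleaned), graph.lookup_synonym(cleaned)):
        if len(hits) == 1:
            doid = next(iter(hits))
            return _with_topnode(doid, graph, label=cleaned)
        if len(hits) > 1:
            return DiseaseNorm(label=cleaned, needs_review=True)
    if shorthand:
        doid = shorthand.get(cleaned) or shorthand.get(cleaned.upper())
        if doid and doid in graph:
            return _with_topnode(doid, graph, label=cleaned)
    return DiseaseNorm(label=cleaned)


def _with_topnode(doid: str, graph: OntologyGraph, label: str) -> DiseaseNorm:
    top = assign_topnode(doid, graph)
    if top is None:
        status = DiseaseMappingStatus.MAPPED
    elif top == graph.root_cancer and graph.root_cancer not in graph.topnode_set \
            and doid != graph.root_cancer:
        status = DiseaseMappingStatus.FALLBACK_CANCER
    else:
        status = DiseaseMappingStatus.MAPPED
    return DiseaseNorm(doid=doid, label=label, topnode=top, mapping_status=status)


def assign_topnode(doid: str, graph: OntologyGraph) -> Optional[str]:
    """Nearest TopNode ancestor-or-self of a disease term.

    Nearest is by minimal is-a path length; ties break to the
    lexicographically smallest identifier. A cancer-branch term with no
    TopNode ancestor falls back to the cancer root (DOID:162); terms outside
    the cancer branch get no assignment.
    """
    if doid not in graph.graph:
        raise UnknownTermError(doid)
    lengths = nx.single_source_shortest_path_length(graph.graph, doid)
    candidates = [(d, t) for t, d in lengths.items() if t in graph.topnode_set]
    if candidates:
        return min(candidates)[1]
    if graph.root_cancer in lengths:
        return graph.root_cancer
    return None


def disease_distance(
    query_doid: str, target_doid: str, graph: OntologyGraph
) -> Optional[int]:
    """Lineage distance between two disease terms, or None for no-match.

    Terms match only if identical or in an ancestor/descendant relationship;
    sibling terms never match, even inside one TopNode subtree. The distance
    is the number of TopNode-set members strictly between the two along the
    lineage, minimized over paths when the DAG offers several — so any
    matching pair inside a single TopNode subtree scores 0.
    """
    for d in (query_doid, target_doid):
        if d not in graph.graph:
            raise UnknownTermError(d)
    if query_doid == target_doid:
        return 0
    if graph.is_ancestor(target_doid, query_doid):
        lower, upper = query_doid, target_doid
    elif graph.is_ancestor(query_doid, target_doid):
        lower, upper = target_doid, query_doid
    else:
        return None
    return _min_topnodes_between(graph, lower, upper)


def _min_topnodes_between(graph: OntologyGraph, lower: str, upper: str) -> int:
    """Min count of TopNode terms strictly between lower and upper on a path."""

    @functools.lru_cache(maxsize=None)
    def best(node: str) -> Optional[int]:
        if node == upper:
            return 0
        costs = []
        for parent in graph.graph.successors(node):
            sub = best(parent)
            if sub is None:
                continue
            hop = 1 if (parent in graph.topnode_set and parent != upper) else 0
            costs.append(hop + sub)
        return min(costs) if costs else None

    result = best(lower)
    assert result is not None  # caller established lineage
    return result
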