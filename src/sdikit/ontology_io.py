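"""OBO parsing into a cellular-component DAG with typed is_a / part_of edges.

Only the two edge types traversed by Wang's similarity measure are kept;
every other relationship type (``regulates``, ``occurs_in``, ...) is dropped
with a logged count. Obsolete terms never enter the graph. Edges point from
child to parent, so "ancestors of t" are the nodes reachable from t.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import networkx as nx

from sdikit.errors import CyclicOntologyError, EmptyOntologyError, UnknownTermError

logger = logging.getLogger(__name__)

#: relation kinds retained in the DAG
RELATIONS = ("is_a", "part_of")


@dataclass
class OntologyDag:
    """A rooted DAG of ontology terms with typed child->parent edges.

    Attributes
    ----------
    graph:
        Directed graph; an edge ``(child, parent)`` carries a ``relation``
        attribute, one of ``"is_a"`` / ``"part_of"``.
    namespace:
        Ontology namespace tag (e.g. ``"cellular_component"``).
    alt_id_map:
        Alias identifier -> canonical identifier.
    obsolete:
        Identifiers marked obsolete in the source file (not in the graph).
    """

    graph: nx.DiGraph
    namespace: str
    alt_id_map: dict[str, str] = field(default_factory=dict)
    obsolete: set[str] = field(default_factory=set)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def __contains__(self, term: str) -> bool:
        return self.resolve(term) is not None

    def resolve(self, term: str) -> str | None:
        """Map an identifier (possibly an alt_id) to its canonical form.

        Returns ``None`` for identifiers absent from the graph.
        """
        if term in self.graph:
            return term
        canonical = self.alt_id_map.get(term)
        if canonical is not None and canonical in self.graph:
            return canonical
        return None

    def require(self, term: str) -> str:
        """Like :meth:`resolve` but raising :class:`UnknownTermError`."""
        canonical = self.resolve(term)
        if canonical is None:
            raise UnknownTermError(term)
        return canonical


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def _stanzas(lines: Iterator[str]) -> Iterator[dict[str, list[str]]]:
    """Yield [Term] stanzas as tag -> list-of-values maps."""
    current: dict[str, list[str]] | None = None
    for raw in lines:
        line = raw.split("!")[0].strip() if not raw.startswith("!") else ""
        if not line:
            continue
        if line.startswith("["):
            if current is not None:
                yield current
            current = {} if line == "[Term]" else None
            continue
        if current is None:
            continue
        tag, _, value = line.partition(":")
        current.setdefault(tag.strip(), []).append(value.strip())
    if current is not None:
        yield current


def parse_obo(path: str | Path, namespace: str = "cellular_component") -> OntologyDag:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyDag`.

    Keeps exactly the non-obsolete ``[Term]`` stanzas of `namespace`;
    captures ``is_a`` and ``relationship: part_of`` links as labeled edges
    and silently drops every other relationship type (count logged).

    Raises
    ------
    OSError
        If the file cannot be read.
    EmptyOntologyError
        If no term matches the namespace.
    CyclicOntologyError
        If the retained edges contain a cycle.
    """
    graph = nx.DiGraph()
    alt_id_map: dict[str, str] = {}
    obsolete: set[str] = set()
    pending_edges: list[tuple[str, str, str]] = []
    dropped_relations = 0

    with _open_text(path) as handle:
        for stanza in _stanzas(handle):
            ids = stanza.get("id")
            if not ids:
                continue
            term_id = ids[0]
            if stanza.get("is_obsolete", ["false"])[0] == "true":
                obsolete.add(term_id)
                continue
            if stanza.get("namespace", [""])[0] != namespace:
                continue
            graph.add_node(term_id, name=stanza.get("name", [""])[0])
            for alt in stanza.get("alt_id", []):
                alt_id_map[alt] = term_id
            for parent in stanza.get("is_a", []):
                pending_edges.append((term_id, parent, "is_a"))
            for rel in stanza.get("relationship", []):
                parts = rel.split()
                if len(parts) != 2:
                    continue
                kind, parent = parts
                if kind == "part_of":
                    pending_edges.append((term_id, parent, "part_of"))
                else:
                    dropped_relations += 1

    if graph.number_of_nodes() == 0:
        raise EmptyOntologyError(f"no terms with namespace {namespace!r} in {path}")

    for child, parent, relation in pending_edges:
        if parent not in graph:  # cross-namespace / obsolete parents dropped
            continue
        if graph.has_edge(child, parent) and graph.edges[child, parent]["relation"] != relation:
            # both is_a and part_of asserted for one pair: keep both labels,
            # the similarity recurrence takes the max weighted contribution
            graph.edges[child, parent]["alt_relation"] = relation
        else:
            graph.add_edge(child, parent, relation=relation)

    if dropped_relations:
        logger.info("dropped %d non-is_a/part_of relationships", dropped_relations)

    if not nx.is_directed_acyclic_graph(graph):
        member = next(iter(nx.find_cycle(graph)))[0]
        raise CyclicOntologyError(member)

    alt_id_map = {a: c for a, c in alt_id_map.items() if c in graph}
    return OntologyDag(graph=graph, namespace=namespace, alt_id_map=alt_id_map, obsolete=obsolete)


def induced_ancestor_graph(dag: OntologyDag, term: str) -> OntologyDag:
    """Sub-DAG of `term`, all its ancestors, and every edge among them.

    This is the term's ancestor graph in Wang's construction: node set
    T_A = {term} ∪ ancestors(term), edge set E_A = all retained edges
    with both endpoints in T_A.
    """
    canonical = dag.require(term)
    nodes = {canonical} | nx.descendants(dag.graph, canonical)
    sub = dag.graph.subgraph(nodes).copy()
    return OntologyDag(graph=sub, namespace=dag.namespace)


def write_obo(dag: OntologyDag, path: str | Path) -> None:
    """Serialize a DAG back to a minimal, deterministic OBO file."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(dag.graph.nodes):
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.graph.nodes[term].get('name', term)}")
        lines.append(f"namespace: {dag.namespace}")
        for alt, canonical in sorted(dag.alt_id_map.items()):
            if canonical == term:
                lines.append(f"alt_id: {alt}")
        for _, parent, data in sorted(dag.graph.out_edges(term, data=True)):
            relations = {data["relation"], data.get("alt_relation", data["relation"])}
            if "is_a" in relations:
                lines.append(f"is_a: {parent}")
            if "part_of" in relations:
                lines.append(f"relationship: part_of {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")
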