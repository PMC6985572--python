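"""Wang's graph-based semantic similarity between ontology terms.

Each term A induces an ancestor graph; every node t in it receives a
semantic contribution S_A(t) by a max-product recurrence over edge
contribution factors (S_A(A)=1, and S_A(t) is the max over children t' of
t inside the graph of w_e * S_A(t')). The semantic value SV(A) sums all
contributions, and the similarity of A and B is the shared-contribution
ratio sum_{t in both}(S_A(t)+S_B(t)) / (SV(A)+SV(B)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from sdikit.ontology_io import OntologyDag, induced_ancestor_graph


@dataclass(frozen=True)
class SimilarityConfig:
    """Edge contribution factors; 0.8 / 0.6 are the recommended values."""

    w_is_a: float = 0.8
    w_part_of: float = 0.6

    def __post_init__(self):
        if not (0.0 < self.w_is_a < 1.0):
            raise ValueError(f"w_is_a must lie in (0,1), got {self.w_is_a}")
        if not (0.0 < self.w_part_of < 1.0):
            raise ValueError(f"w_part_of must lie in (0,1), got {self.w_part_of}")

    def weight(self, relation: str) -> float:
        return self.w_is_a if relation == "is_a" else self.w_part_of

    def edge_weight(self, data: dict) -> float:
        """Max weighted factor over every label carried by one edge."""
        w = self.weight(data["relation"])
        if "alt_relation" in data:
            w = max(w, self.weight(data["alt_relation"]))
        return w


@dataclass
class TermSemanticProfile:
    """Per-ancestor semantic contributions of one term and their sum."""

    term: str
    s_values: dict[str, float]
    sv: float = field(init=False)

    def __post_init__(self):
        self.sv = sum(self.s_values.values())


def semantic_profile(
    dag: OntologyDag, term: str, config: SimilarityConfig = SimilarityConfig()
) -> TermSemanticProfile:
    """Compute S-values for `term` over its induced ancestor graph.

    Dynamic programming in topological order (children before parents);
    parallel is_a/part_of edges between the same pair take the max of
    both weighted contributions.
    """
    sub = induced_ancestor_graph(dag, term)
    canonical = dag.require(term)
    s_values: dict[str, float] = {canonical: 1.0}
    # edges point child->parent, so a topological sort emits descendants first
    for node in nx.topological_sort(sub.graph):
        if node == canonical:
            continue
        best = 0.0
        for child, _, data in sub.graph.in_edges(node, data=True):
            candidate = config.edge_weight(data) * s_values[child]
            if candidate > best:
                best = candidate
        s_values[node] = best
    return TermSemanticProfile(term=canonical, s_values=s_values)


def similarity(
    dag: OntologyDag,
    a: str,
    b: str,
    config: SimilarityConfig = SimilarityConfig(),
    _cache: dict[str, TermSemanticProfile] | None = None,
) -> float:
    """Wang's similarity of terms `a` and `b`, in [0, 1].

    Exactly 1.0 for identical terms; 0.0 when the ancestor graphs share
    no term (possible only across disconnected components). The optional
    `_cache` maps canonical term -> profile and must be scoped to a single
    (dag, config) pair; caching never changes the result.
    """
    ca, cb = dag.require(a), dag.require(b)
    if ca == cb:
        return 1.0

    def profile(t: str) -> TermSemanticProfile:
        if _cache is not None:
            if t not in _cache:
                _cache[t] = semantic_profile(dag, t, config)
            return _cache[t]
        return semantic_profile(dag, t, config)

    pa, pb = profile(ca), profile(cb)
    shared = pa.s_values.keys() & pb.s_values.keys()
    if not shared:
        return 0.0
    numerator = sum(pa.s_values[t] + pb.s_values[t] for t in shared)
    return numerator / (pa.sv + pb.sv)


def write_similarity_tsv(
    dag: OntologyDag,
    pairs: list[tuple[str, str]],
    path,
    config: SimilarityConfig = SimilarityConfig(),
) -> None:
    """Debug dump: one (term_a, term_b, similarity) row per requested pair."""
    cache: dict[str, TermSemanticProfile] = {}
    with open(path, "w", encoding="utf-8") as out:
        out.write("term_a\tterm_b\tsimilarity\n")
        for a, b in pairs:
            s = similarity(dag, a, b, config, _cache=cache)
            out.write(f"{a}\t{b}\t{s!r}\n")
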