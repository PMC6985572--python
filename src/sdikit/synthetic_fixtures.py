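"""Synthetic ontologies, annotation tables, labels and feature tables.

Everything here is a pure function of (spec, seed): fixtures are
deterministic, serializable to the same plain-text formats the real
pipeline consumes (OBO, gene2go TSV, label lists, feature TSVs), and
guaranteed to round-trip through the corresponding parsers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from sdikit.annotation_io import GeneAnnotation
from sdikit.errors import FixtureSpecError
from sdikit.ontology_io import OntologyDag
from sdikit.sdi_core import SdiResult


@dataclass
class FixtureSpec:
    n_terms: int = 30
    depth: int = 4
    part_of_fraction: float = 0.3
    n_genes: int = 100
    term_count_range: tuple[int, int] = (1, 5)
    label_model: tuple[float, float] = (-2.0, 0.8)  # (alpha, beta) of the logistic
    iea_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 1:
            raise FixtureSpecError("n_terms must be >= 1")
        if self.depth < 1:
            raise FixtureSpecError("depth must be >= 1")
        if self.depth > self.n_terms:
            raise FixtureSpecError("depth cannot exceed n_terms")
        if not (0.0 <= self.part_of_fraction <= 1.0):
            raise FixtureSpecError("part_of_fraction must lie in [0, 1]")
        if self.term_count_range[0] < 1:
            raise FixtureSpecError("term_count_range lower bound must be >= 1")


def _term_id(i: int) -> str:
    return f"GO:{i + 1:07d}"


def make_ontology(spec: FixtureSpec) -> OntologyDag:
    """A connected, single-rooted DAG built level by level.

    Term 0 is the root at level 0; every other term sits at a level in
    [1, depth-1] (or 1 when depth == 1 would leave no room) and receives
    1-2 parents from strictly shallower levels, which rules out cycles by
    construction. Edge labels are drawn is_a / part_of with probability
    (1 - part_of_fraction) / part_of_fraction.
    """
    rng = np.random.default_rng(spec.seed)
    graph = nx.DiGraph()
    root = _term_id(0)
    graph.add_node(root, name="term_0000001")
    if spec.n_terms == 1:
        return OntologyDag(graph=graph, namespace="cellular_component")

    max_level = max(spec.depth - 1, 1)
    levels: dict[int, list[str]] = {0: [root]}
    # guarantee every level is populated so max depth is attained
    assigned = [1 + (i % max_level) for i in range(spec.n_terms - 1)]
    rng.shuffle(assigned)
    for i, level in enumerate(assigned, start=1):
        term = _term_id(i)
        graph.add_node(term, name=f"term_{i + 1:07d}")
        shallower = [t for lvl in range(level) for t in levels.get(lvl, [])]
        n_parents = min(int(rng.integers(1, 3)), len(shallower))
        parents = rng.choice(shallower, size=n_parents, replace=False)
        for parent in parents:
            relation = "part_of" if rng.random() < spec.part_of_fraction else "is_a"
            graph.add_edge(term, parent, relation=relation)
        levels.setdefault(level, []).append(term)
    return OntologyDag(graph=graph, namespace="cellular_component")


def make_annotations(
    dag: OntologyDag, spec: FixtureSpec, taxon: str = "9606"
) -> tuple[dict[str, GeneAnnotation], list[str]]:
    """Random per-gene term sets plus the gene2go-format lines encoding them.

    Each gene draws a uniform term-set size from ``term_count_range``
    (clamped to the ontology size) and samples terms without replacement;
    a fraction ``iea_fraction`` of genes is tagged with the IEA evidence
    code, the rest with IDA.
    """
    rng = np.random.default_rng(spec.seed + 1)
    terms = sorted(dag.terms)
    lo = min(spec.term_count_range[0], len(terms))
    hi = min(spec.term_count_range[1], len(terms))

    annotations: dict[str, GeneAnnotation] = {}
    lines = ["#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory"]
    for g in range(spec.n_genes):
        gene_id = str(1000 + g)
        k = int(rng.integers(lo, hi + 1))
        chosen = sorted(rng.choice(terms, size=k, replace=False).tolist())
        annotations[gene_id] = GeneAnnotation(gene_id, frozenset(chosen))
        evidence = "IEA" if rng.random() < spec.iea_fraction else "IDA"
        for term in chosen:
            name = dag.graph.nodes[term].get("name", term)
            lines.append(
                f"{taxon}\t{gene_id}\t{term}\t{evidence}\t-\t{name}\t-\tComponent"
            )
    return annotations, lines


def write_gene2go(lines: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def make_labels(
    sdi_results: list[SdiResult],
    label_model: tuple[float, float] = (-2.0, 0.8),
    seed: int = 0,
) -> set[str]:
    """Each gene positive with probability logistic(alpha + beta * sdi)."""
    if not sdi_results:
        raise FixtureSpecError("make_labels requires non-empty results")
    alpha, beta = label_model
    rng = np.random.default_rng(seed)
    positives = set()
    for r in sorted(sdi_results, key=lambda r: r.gene_id):
        p = 1.0 / (1.0 + np.exp(-(alpha + beta * r.sdi)))
        if rng.random() < p:
            positives.add(r.gene_id)
    return positives


def make_feature_table(
    sdi_results: list[SdiResult],
    noise_sd: float = 1.0,
    n_noise_features: int = 1,
    seed: int = 0,
) -> "pd.DataFrame":
    """SDI-informative feature plus pure-noise columns, for CV-logit tests."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    genes = sorted(r.gene_id for r in sdi_results)
    sdi = {r.gene_id: r.sdi for r in sdi_results}
    data = {"sdi_noisy": [sdi[g] + rng.normal(0, noise_sd) for g in genes]}
    for j in range(n_noise_features):
        data[f"noise_{j}"] = rng.normal(0, 1, size=len(genes)).tolist()
    return pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))


def write_label_list(labels: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(labels)) + "\n", encoding="utf-8")
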