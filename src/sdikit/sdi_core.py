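"""The Subcellular Diversity Index: per-gene penalties and the summed score.

For a gene annotated with n cellular-component terms, each term i gets a
penalty p_i aggregating its n-1 pairwise similarities to the other terms
(root mean square by default; arithmetic and geometric means are the
alternative aggregators), and SDI = sum over i of (1 - p_i). A gene with
a single term has penalty 1 and SDI 0 by definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

from sdikit.annotation_io import GeneAnnotation
from sdikit.errors import ContractViolationError, DomainError, UnknownTermError
from sdikit.ontology_io import OntologyDag
from sdikit.wang_similarity import SimilarityConfig, TermSemanticProfile, similarity

Aggregator = Literal["rms", "arithmetic_mean", "geometric_mean"]

AGGREGATORS: tuple[str, ...] = ("rms", "arithmetic_mean", "geometric_mean")


@dataclass(frozen=True)
class SdiConfig:
    aggregator: str = "rms"
    similarity_config: SimilarityConfig = field(default_factory=SimilarityConfig)
    quartile_method: str = "linear"  # numpy quantile method; "linear" = type-7

    def __post_init__(self):
        if self.aggregator not in AGGREGATORS:
            raise ValueError(
                f"aggregator must be one of {AGGREGATORS}, got {self.aggregator!r}"
            )


@dataclass
class SdiResult:
    """Per-gene penalty vector (in lexicographic term order) and SDI score."""

    gene_id: str
    terms: tuple[str, ...]
    penalties: tuple[float, ...]
    sdi: float

    @property
    def n(self) -> int:
        return len(self.terms)


def penalty(similarities_to_others: Iterable[float], aggregator: str = "rms") -> float:
    """Aggregate a term's similarities to its gene's other terms into [0, 1].

    rms -> sqrt(mean of squares); arithmetic_mean -> mean;
    geometric_mean -> (prod s_j)^(1/k), with the 0-annihilation limit
    convention when any s_j is 0.
    """
    values = list(similarities_to_others)
    if not values:
        raise ContractViolationError("penalty requires at least one similarity")
    for s in values:
        if not (0.0 <= s <= 1.0):
            raise DomainError(f"similarity {s} outside [0, 1]")
    if aggregator == "rms":
        return math.sqrt(sum(s * s for s in values) / len(values))
    if aggregator == "arithmetic_mean":
        return sum(values) / len(values)
    if aggregator == "geometric_mean":
        if any(s == 0.0 for s in values):
            return 0.0
        return math.exp(sum(math.log(s) for s in values) / len(values))
    raise ValueError(f"unknown aggregator {aggregator!r}")


def gene_sdi(
    annotation: GeneAnnotation,
    dag: OntologyDag,
    config: SdiConfig = SdiConfig(),
    _cache: dict[str, TermSemanticProfile] | None = None,
) -> SdiResult:
    """Score one gene. Penalties follow lexicographic term order."""
    try:
        terms = tuple(sorted(dag.require(t) for t in annotation.terms))
    except UnknownTermError as err:
        raise UnknownTermError(err.term, gene_id=annotation.gene_id) from None

    if len(terms) == 1:
        return SdiResult(annotation.gene_id, terms, (1.0,), 0.0)

    sim: dict[tuple[str, str], float] = {}
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            sim[(a, b)] = similarity(dag, a, b, config.similarity_config, _cache=_cache)

    penalties = []
    for a in terms:
        sims = [sim[(min(a, b), max(a, b))] for b in terms if b != a]
        penalties.append(penalty(sims, config.aggregator))
    sdi = sum(1.0 - p for p in penalties)
    return SdiResult(annotation.gene_id, terms, tuple(penalties), sdi)


def score_genome(
    annotations: Iterable[GeneAnnotation],
    dag: OntologyDag,
    config: SdiConfig = SdiConfig(),
    strict: bool = True,
) -> tuple[list[SdiResult], dict[str, float]]:
    """Score every gene and summarize the SDI distribution.

    Results come back sorted by gene_id, so output is independent of the
    input iteration order. `strict=False` skips genes with unresolvable
    terms instead of aborting.

    The summary carries minimum, first quartile, median, mean, third
    quartile, maximum and gene count (quartile convention set by
    ``config.quartile_method``).
    """
    cache: dict[str, TermSemanticProfile] = {}
    results: list[SdiResult] = []
    for ann in sorted(annotations, key=lambda a: a.gene_id):
        try:
            results.append(gene_sdi(ann, dag, config, _cache=cache))
        except UnknownTermError:
            if strict:
                raise
    return results, summarize(results, method=config.quartile_method)


def summarize(results: list[SdiResult], method: str = "linear") -> dict[str, float]:
    if not results:
        return {
            "minimum": float("nan"), "q1": float("nan"), "median": float("nan"),
            "mean": float("nan"), "q3": float("nan"), "maximum": float("nan"),
            "gene_number": 0,
        }
    scores = np.array([r.sdi for r in results])
    q1, med, q3 = (float(np.quantile(scores, q, method=method)) for q in (0.25, 0.5, 0.75))
    return {
        "minimum": float(scores.min()),
        "q1": q1,
        "median": med,
        "mean": float(scores.mean()),
        "q3": q3,
        "maximum": float(scores.max()),
        "gene_number": len(results),
    }


def write_scores_tsv(
    results: list[SdiResult], path: str | Path, full_precision: bool = False
) -> None:
    """gene_id / n_terms / sdi table; 3-decimal display unless full precision."""
    with open(path, "w", encoding="utf-8") as out:
        out.write("gene_id\tn_terms\tsdi\n")
        for r in results:
            value = repr(r.sdi) if full_precision else f"{r.sdi:.3f}"
            out.write(f"{r.gene_id}\t{r.n}\t{value}\n")


def write_summary_tsv(summary: dict[str, float], path: str | Path) -> None:
    cols = ["minimum", "q1", "median", "mean", "q3", "maximum", "gene_number"]
    with open(path, "w", encoding="utf-8") as out:
        out.write("\t".join(cols) + "\n")
        cells = []
        for c in cols:
            v = summary[c]
            cells.append(str(int(v)) if c == "gene_number" else f"{v:.3f}")
        out.write("\t".join(cells) + "\n")


def read_scores_tsv(path: str | Path) -> dict[str, float]:
    """Read a score TSV back as gene_id -> sdi."""
    scores: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as handle:
        header = handle.readline()
        if not header.startswith("gene_id"):
            raise ValueError(f"{path}: not a score TSV")
        for line in handle:
            gene_id, _, value = line.rstrip("\n").split("\t")
            scores[gene_id] = float(value)
    return scores
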