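"""Validation battery: ROC/AUC, decile enrichment, correlations, CV logistic
regression, and the random-term-replacement sensitivity analysis."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from sdikit.annotation_io import GeneAnnotation
from sdikit.errors import ContractViolationError, UndefinedStatisticError
from sdikit.ontology_io import OntologyDag
from sdikit.sdi_core import SdiConfig, score_genome

logger = logging.getLogger(__name__)


@dataclass
class LabelSet:
    """Named set of positive gene identifiers (essential genes, drug targets...)."""

    name: str
    positives: set[str]

    def __post_init__(self):
        if not self.positives:
            raise ValueError(f"label set {self.name!r} is empty")


@dataclass
class PerturbationSpec:
    """Parameters of the random-term-replacement perturbation."""

    fraction: float
    term_count_range: tuple[int, int] = (1, 45)
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError(f"fraction must lie in (0, 1], got {self.fraction}")
        if self.term_count_range[0] < 1 or self.term_count_range[0] > self.term_count_range[1]:
            raise ValueError(f"bad term_count_range {self.term_count_range}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _align(scores: dict[str, float], labels: LabelSet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    genes = sorted(scores)
    y = np.array([g in labels.positives for g in genes], dtype=int)
    x = np.array([scores[g] for g in genes], dtype=float)
    return x, y, genes


def roc_auc(scores: dict[str, float], labels: LabelSet) -> dict:
    """AUC as the rank statistic (ties count one half) plus the ROC polyline.

    Evaluated on the intersection of scored genes and the label universe;
    higher score predicts positive.
    """
    x, y, genes = _align(scores, labels)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise UndefinedStatisticError(
            f"AUC undefined: {n_pos} positives among {len(y)} scored genes"
        )
    auc = float(roc_auc_score(y, x))
    fpr, tpr, _ = roc_curve(y, x)
    return {
        "auc": auc,
        "roc_points": list(zip(fpr.tolist(), tpr.tolist())),
        "n_genes": len(y),
        "n_positives": n_pos,
    }


def decile_groups(scores: dict[str, float], n_groups: int = 10) -> list[list[str]]:
    """Split genes into contiguous rank groups, ascending by score.

    Ties break on gene_id so assignment is deterministic. Group sizes
    differ by at most one; the remainder goes to the lowest groups.
    """
    genes = sorted(scores, key=lambda g: (scores[g], g))
    n = len(genes)
    if n < n_groups:
        raise ContractViolationError(f"need >= {n_groups} genes, got {n}")
    base, rem = divmod(n, n_groups)
    groups, start = [], 0
    for i in range(n_groups):
        size = base + (1 if i < rem else 0)
        groups.append(genes[start : start + size])
        start += size
    return groups


def decile_enrichment(scores: dict[str, float], labels: LabelSet) -> dict:
    """Per-decile positive counts and the Pearson chi-square of the 2x10 table."""
    groups = decile_groups(scores)
    pos = [sum(g in labels.positives for g in grp) for grp in groups]
    tot = [len(grp) for grp in groups]
    table = np.array([pos, [t - p for t, p in zip(tot, pos)]])
    if table.sum(axis=1).min() == 0:
        raise UndefinedStatisticError("degenerate 2x10 table: an empty row")
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {
        "decile_positives": pos,
        "decile_totals": tot,
        "chi_square": float(chi2),
        "chi_square_p": float(p),
        "dof": int(dof),
    }


def spearman(scores: dict[str, float], feature: dict[str, float]) -> dict:
    """Spearman rho (average-rank ties) with two-sided p on the gene intersection."""
    genes = sorted(set(scores) & set(feature))
    if len(genes) < 3:
        raise ContractViolationError(f"need >= 3 shared genes, got {len(genes)}")
    x = np.array([scores[g] for g in genes])
    y = np.array([feature[g] for g in genes])
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedStatisticError("correlation undefined on a constant vector")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n_genes": len(genes)}


def cv_logistic(
    features: pd.DataFrame,
    labels: LabelSet,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Cross-validated logistic-regression AUC per single feature and all-features.

    Complete-case genes only. Stratified k-fold; models fit on train folds,
    held-out predicted probabilities pooled across folds, one AUC per model.
    A fold degenerating to a single class triggers a reseeded refold (up to
    5 attempts).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    df = features.dropna()
    y = np.array([g in labels.positives for g in df.index], dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise UndefinedStatisticError("labels are single-class on complete-case genes")

    models = {col: [col] for col in df.columns}
    if len(df.columns) > 1:
        models["all_features"] = list(df.columns)

    out: dict[str, float] = {}
    for name, cols in models.items():
        X = df[cols].to_numpy(dtype=float)
        out[name] = _pooled_cv_auc(X, y, folds, seed)
    return out


def _pooled_cv_auc(X: np.ndarray, y: np.ndarray, folds: int, seed: int) -> float:
    last_err: Exception | None = None
    for attempt in range(5):
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        pred = np.empty(len(y))
        try:
            for train, test in cv.split(X, y):
                if len(np.unique(y[train])) < 2 or len(np.unique(y[test])) < 2:
                    raise UndefinedStatisticError("single-class fold")
                model = LogisticRegression(max_iter=1000)
                model.fit(X[train], y[train])
                pred[test] = model.predict_proba(X[test])[:, 1]
            return float(roc_auc_score(y, pred))
        except UndefinedStatisticError as err:
            last_err = err
    raise UndefinedStatisticError(f"could not build valid folds after 5 attempts: {last_err}")


def perturb_annotations(
    annotations: dict[str, GeneAnnotation],
    dag: OntologyDag,
    spec: PerturbationSpec,
) -> list[dict[str, GeneAnnotation]]:
    """Per replicate: replace the whole term set of a random gene subset.

    A fraction ``spec.fraction`` of genes (at least one, rounded up) is
    chosen uniformly; each chosen gene's terms are replaced by k terms
    drawn uniformly without replacement from the ontology, with k uniform
    over ``term_count_range`` (clamped to the ontology size). Unperturbed
    genes are passed through untouched. Fully reproducible from the seed:
    the top-level seed fans out to one child seed per replicate.
    """
    genes = sorted(annotations)
    all_terms = sorted(dag.terms)
    n_perturb = math.ceil(spec.fraction * len(genes))
    if spec.fraction * len(genes) < 1:
        logger.warning("fraction too small for gene count; perturbing 1 gene")
    lo = min(spec.term_count_range[0], len(all_terms))
    hi = min(spec.term_count_range[1], len(all_terms))

    replicates = []
    for child in np.random.SeedSequence(spec.seed).spawn(spec.replicates):
        rng = np.random.default_rng(child)
        chosen = set(rng.choice(genes, size=n_perturb, replace=False))
        perturbed = {}
        for gene in genes:
            if gene in chosen:
                k = int(rng.integers(lo, hi + 1))
                terms = rng.choice(all_terms, size=k, replace=False)
                perturbed[gene] = GeneAnnotation(gene, frozenset(terms.tolist()))
            else:
                perturbed[gene] = annotations[gene]
        replicates.append(perturbed)
    return replicates


def sensitivity_suite(
    annotations: dict[str, GeneAnnotation],
    dag: OntologyDag,
    labels: LabelSet,
    fractions: list[float],
    term_count_range: tuple[int, int] = (1, 45),
    replicates: int = 3,
    seed: int = 0,
    sdi_config: SdiConfig = SdiConfig(),
) -> dict:
    """Perturb -> rescore -> AUC grid over fractions x replicates.

    Returns the baseline (unperturbed) AUC, one AUC per (fraction,
    replicate) cell, and the per-fraction replicate average — the shape of
    a robustness table. A fraction of 0 reuses the baseline in every cell.
    """
    base_results, _ = score_genome(annotations.values(), dag, sdi_config)
    base_scores = {r.gene_id: r.sdi for r in base_results}
    baseline = roc_auc(base_scores, labels)["auc"]

    grid: dict[float, dict] = {}
    for fi, fraction in enumerate(fractions):
        if fraction == 0:
            cells = [baseline] * replicates
        else:
            spec = PerturbationSpec(
                fraction=fraction,
                term_count_range=term_count_range,
                replicates=replicates,
                seed=seed + 1000 * fi,
            )
            cells = []
            for perturbed in perturb_annotations(annotations, dag, spec):
                results, _ = score_genome(perturbed.values(), dag, sdi_config)
                scores = {r.gene_id: r.sdi for r in results}
                cells.append(roc_auc(scores, labels)["auc"])
        grid[fraction] = {"replicates": cells, "average": float(np.mean(cells))}

    return {"baseline_auc": baseline, "fractions": grid, "seed": seed}


def write_sensitivity_tsv(report: dict, path) -> None:
    """Serialize the sensitivity grid as a fractions-in-columns TSV."""
    fractions = sorted(report["fractions"])
    n_rep = len(report["fractions"][fractions[0]]["replicates"]) if fractions else 0
    with open(path, "w", encoding="utf-8") as out:
        out.write("row\tbaseline\t" + "\t".join(f"{f:g}" for f in fractions) + "\n")
        for r in range(n_rep):
            cells = [f"{report['fractions'][f]['replicates'][r]:.3f}" for f in fractions]
            out.write(f"group_{r + 1}\t\t" + "\t".join(cells) + "\n")
        avg = [f"{report['fractions'][f]['average']:.3f}" for f in fractions]
        out.write(f"average\t{report['baseline_auc']:.3f}\t" + "\t".join(avg) + "\n")
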