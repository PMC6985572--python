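import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import auc_pair_counting
from sdikit.annotation_io import GeneAnnotation
from sdikit.errors import ContractViolationError, UndefinedStatisticError
from sdikit.evaluation import (
    LabelSet,
    PerturbationSpec,
    cv_logistic,
    decile_enrichment,
    decile_groups,
    perturb_annotations,
    roc_auc,
    sensitivity_suite,
    spearman,
)
from sdikit.sdi_core import score_genome
from sdikit.synthetic_fixtures import (
    FixtureSpec,
    make_annotations,
    make_labels,
    make_ontology,
)


def _random_scores_labels(n, seed):
    rng = np.random.default_rng(seed)
    scores = {f"G{i}": float(rng.normal()) for i in range(n)}
    positives = {g for g, s in scores.items() if rng.random() < 1 / (1 + np.exp(-s))}
    if not positives or len(positives) == n:
        return _random_scores_labels(n, seed + 1000)
    return scores, positives


class TestRocAuc:
    def test_perfect_separation(self):
        report = roc_auc({"a": 3.0, "b": 2.0, "c": 1.0}, LabelSet("x", {"a"}))
        assert report["auc"] == 1.0

    def test_all_ties(self):
        report = roc_auc({"a": 1.0, "b": 1.0, "c": 1.0}, LabelSet("x", {"a"}))
        assert report["auc"] == 0.5

    def test_single_class_error(self):
        with pytest.raises(UndefinedStatisticError):
            roc_auc({"a": 1.0, "b": 2.0}, LabelSet("x", {"a", "b"}))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        scores, positives = _random_scores_labels(200, seed)
        report = roc_auc(scores, LabelSet("x", positives))
        assert report["auc"] == pytest.approx(
            auc_pair_counting(scores, positives), abs=1e-12
        )

    def test_complement_symmetry(self):
        scores, positives = _random_scores_labels(100, 42)
        neg = {g: -s for g, s in scores.items()}
        a = roc_auc(scores, LabelSet("x", positives))["auc"]
        b = roc_auc(neg, LabelSet("x", positives))["auc"]
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_roc_points_monotone_and_anchored(self):
        scores, positives = _random_scores_labels(50, 3)
        points = roc_auc(scores, LabelSet("x", positives))["roc_points"]
        fpr = [p[0] for p in points]
        tpr = [p[1] for p in points]
        assert fpr == sorted(fpr) and tpr == sorted(tpr)
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)


class TestDecileEnrichment:
    def test_top_decile_captures_top_positives(self):
        scores = {f"G{i:03d}": float(i) for i in range(100)}
        positives = {f"G{i:03d}" for i in range(90, 100)}
        report = decile_enrichment(scores, LabelSet("x", positives))
        assert report["decile_positives"] == [0] * 9 + [10]
        assert report["decile_totals"] == [10] * 10

    def test_group_sizes_differ_by_at_most_one(self):
        scores = {f"G{i}": float(i) for i in range(103)}
        groups = decile_groups(scores)
        sizes = [len(g) for g in groups]
        assert max(sizes) - min(sizes) <= 1
        assert sum(sizes) == 103
        assert sizes[:3] == [11, 11, 11]  # remainder to the lowest groups

    def test_groups_contiguous_in_rank(self):
        rng = np.random.default_rng(5)
        scores = {f"G{i}": float(rng.normal()) for i in range(57)}
        groups = decile_groups(scores)
        flat = [g for grp in groups for g in grp]
        assert flat == sorted(scores, key=lambda g: (scores[g], g))

    def test_null_labels_give_unremarkable_p(self):
        rng = np.random.default_rng(0)
        scores = {f"G{i}": float(rng.normal()) for i in range(1000)}
        positives = {g for g in scores if rng.random() < 0.3}
        report = decile_enrichment(scores, LabelSet("x", positives))
        assert report["chi_square_p"] > 0.01

    def test_chi_square_matches_textbook_routine(self):
        """Reproduce the test from a printed 2x10 count table."""
        pos = [10, 12, 15, 14, 20, 25, 30, 35, 40, 50]
        tot = [100] * 10
        scores, positives = {}, set()
        k = 0
        for d in range(10):
            for j in range(tot[d]):
                g = f"G{k:04d}"
                scores[g] = float(k)
                if j < pos[d]:
                    positives.add(g)
                k += 1
        report = decile_enrichment(scores, LabelSet("x", positives))
        observed = np.array([pos, [t - p for t, p in zip(tot, pos)]], dtype=float)
        # hand-rolled Pearson statistic
        row = observed.sum(axis=1, keepdims=True)
        col = observed.sum(axis=0, keepdims=True)
        expected = row @ col / observed.sum()
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        assert report["chi_square"] == pytest.approx(chi2, abs=1e-9)
        assert report["chi_square_p"] == pytest.approx(stats.chi2.sf(chi2, 9), abs=1e-12)

    def test_too_few_genes(self):
        with pytest.raises(ContractViolationError):
            decile_enrichment({f"G{i}": float(i) for i in range(9)}, LabelSet("x", {"G1"}))


class TestSpearman:
    def test_identity_and_negation(self):
        scores = {f"G{i}": float(i) for i in range(20)}
        assert spearman(scores, scores)["rho"] == pytest.approx(1.0)
        neg = {g: -v for g, v in scores.items()}
        assert spearman(scores, neg)["rho"] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self):
        rng = np.random.default_rng(8)
        scores = {f"G{i}": float(rng.normal()) for i in range(50)}
        feature = {f"G{i}": float(rng.normal()) for i in range(50)}
        report = spearman(scores, feature)
        genes = sorted(scores)
        rx = stats.rankdata([scores[g] for g in genes])
        ry = stats.rankdata([feature[g] for g in genes])
        assert report["rho"] == pytest.approx(float(np.corrcoef(rx, ry)[0, 1]), abs=1e-12)

    def test_intersection_only(self):
        scores = {"G1": 1.0, "G2": 2.0, "G3": 3.0, "G4": 4.0}
        feature = {"G2": 5.0, "G3": 6.0, "G4": 7.0, "G9": 0.0}
        assert spearman(scores, feature)["n_genes"] == 3

    def test_constant_vector_error(self):
        scores = {f"G{i}": 1.0 for i in range(10)}
        feature = {f"G{i}": float(i) for i in range(10)}
        with pytest.raises(UndefinedStatisticError):
            spearman(scores, feature)


class TestCvLogistic:
    def test_self_predicting_feature(self):
        rng = np.random.default_rng(1)
        score = rng.normal(size=400)
        y = rng.random(400) < 1 / (1 + np.exp(-4 * score))
        df = pd.DataFrame({"f": score}, index=[f"G{i}" for i in range(400)])
        labels = LabelSet("x", {f"G{i}" for i in range(400) if y[i]})
        out = cv_logistic(df, labels, folds=10, seed=0)
        assert out["f"] > 0.9

    def test_pure_noise_feature(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"f": rng.normal(size=500)}, index=[f"G{i}" for i in range(500)])
        labels = LabelSet("x", {f"G{i}" for i in range(500) if rng.random() < 0.4})
        out = cv_logistic(df, labels, folds=10, seed=0)
        assert 0.4 <= out["f"] <= 0.6

    def test_all_features_model_at_least_best_single(self):
        rng = np.random.default_rng(3)
        f1 = rng.normal(size=800)
        f2 = rng.normal(size=800)
        y = rng.random(800) < 1 / (1 + np.exp(-(f1 + f2)))
        df = pd.DataFrame({"f1": f1, "f2": f2}, index=[f"G{i}" for i in range(800)])
        labels = LabelSet("x", {f"G{i}" for i in range(800) if y[i]})
        out = cv_logistic(df, labels, folds=10, seed=0)
        assert "all_features" in out
        assert out["all_features"] >= max(out["f1"], out["f2"]) - 0.02

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"f": rng.normal(size=100)}, index=[f"G{i}" for i in range(100)])
        labels = LabelSet("x", {f"G{i}" for i in range(0, 100, 3)})
        assert cv_logistic(df, labels, seed=7) == cv_logistic(df, labels, seed=7)


class TestPerturbAnnotations:
    @pytest.fixture
    def setup(self):
        spec = FixtureSpec(n_terms=30, n_genes=50, term_count_range=(1, 5), seed=6)
        dag = make_ontology(spec)
        annotations, _ = make_annotations(dag, spec)
        return dag, annotations

    def test_full_fraction_single_term(self, setup):
        dag, annotations = setup
        spec = PerturbationSpec(fraction=1.0, term_count_range=(1, 1), replicates=1, seed=0)
        (perturbed,) = perturb_annotations(annotations, dag, spec)
        assert all(ann.n == 1 for ann in perturbed.values())
        results, _ = score_genome(perturbed.values(), dag)
        assert all(r.sdi == 0.0 for r in results)

    def test_same_seed_reproducible(self, setup):
        dag, annotations = setup
        spec = PerturbationSpec(fraction=0.2, replicates=2, seed=5)
        a = perturb_annotations(annotations, dag, spec)
        b = perturb_annotations(annotations, dag, spec)
        assert a == b

    def test_exact_perturbation_count(self, setup):
        dag, annotations = setup
        spec = PerturbationSpec(fraction=0.1, replicates=3, seed=1)
        for perturbed in perturb_annotations(annotations, dag, spec):
            changed = [
                g for g in annotations if perturbed[g] is not annotations[g]
            ]
            assert len(changed) == 5  # ceil(0.1 * 50)
            untouched = [g for g in annotations if perturbed[g] is annotations[g]]
            assert len(untouched) == 45

    def test_replicates_differ(self, setup):
        dag, annotations = setup
        spec = PerturbationSpec(fraction=0.5, replicates=2, seed=2)
        r1, r2 = perturb_annotations(annotations, dag, spec)
        assert r1 != r2

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PerturbationSpec(fraction=0.0)
        with pytest.raises(ValueError):
            PerturbationSpec(fraction=0.1, term_count_range=(0, 5))


@pytest.fixture(scope="module")
def pipeline():
    spec = FixtureSpec(n_terms=40, depth=5, n_genes=150, term_count_range=(1, 6), seed=10)
    dag = make_ontology(spec)
    annotations, _ = make_annotations(dag, spec)
    results, _ = score_genome(annotations.values(), dag)
    positives = make_labels(results, (-2.0, 1.5), seed=11)
    return dag, annotations, LabelSet("essential", positives)


class TestSensitivitySuite:

    def test_fraction_zero_equals_baseline(self, pipeline):
        dag, annotations, labels = pipeline
        report = sensitivity_suite(annotations, dag, labels, fractions=[0], replicates=3)
        cells = report["fractions"][0]["replicates"]
        assert cells == [report["baseline_auc"]] * 3

    def test_average_is_mean_of_replicates(self, pipeline):
        dag, annotations, labels = pipeline
        report = sensitivity_suite(
            annotations, dag, labels, fractions=[0.1], replicates=3, seed=3
        )
        cell = report["fractions"][0.1]
        assert cell["average"] == pytest.approx(np.mean(cell["replicates"]))

    def test_auc_degrades_with_fraction(self, pipeline):
        dag, annotations, labels = pipeline
        report = sensitivity_suite(
            annotations, dag, labels,
            fractions=[0.05, 0.20, 0.60], replicates=3, seed=4,
            term_count_range=(1, 6),
        )
        small = report["fractions"][0.05]["average"]
        large = report["fractions"][0.60]["average"]
        assert report["baseline_auc"] >= small - 0.02
        assert small >= large - 0.02

    def test_same_seed_identical_grid(self, pipeline):
        dag, annotations, labels = pipeline
        kwargs = dict(fractions=[0.1], replicates=2, seed=9)
        a = sensitivity_suite(annotations, dag, labels, **kwargs)
        b = sensitivity_suite(annotations, dag, labels, **kwargs)
        assert a == b
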