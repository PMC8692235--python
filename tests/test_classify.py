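"""Quadratic discriminant classifier, cross-validation, and ROC-AUC."""

import numpy as np
import pytest

from myospec.classify import (
    CVResult,
    crossval_fivefold,
    decision_boundary_grid,
    fit_qdc,
    make_folds,
    multiclass_auc,
    posterior,
    predict,
    roc_auc,
)
from myospec.features import ScoreMatrix


def gaussian_scores(rng, means, n_per_class, sd=1.0):
    """Score clouds: one isotropic Gaussian per class."""
    xs, ys = [], []
    for name, mu in means.items():
        xs.append(rng.normal(0, sd, size=(n_per_class, len(mu))) + np.asarray(mu))
        ys.extend([name] * n_per_class)
    return ScoreMatrix(np.vstack(xs), ys)


def concordance_auc(pos_scores, neg_scores):
    """Brute-force pairwise concordance: P(s+ > s-) + 1/2 P(s+ = s-)."""
    total = 0.0
    for p in pos_scores:
        for n in neg_scores:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos_scores) * len(neg_scores))


def cv_from_binary_scores(pos, neg):
    """Wrap raw positive-class scores as a pooled CV result."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    y = np.array(["pos"] * len(pos) + ["neg"] * len(neg))
    score = np.concatenate([pos, neg])
    post = np.column_stack([1 - score, score])  # classes sorted: neg, pos
    return CVResult(
        classes=["neg", "pos"],
        y=y,
        fold_assignments=np.ones(len(y), dtype=int),
        held_out_posteriors=post,
        seed=0,
        n_folds=1,
    )


class TestFitQDC:
    def test_equal_identity_covariances_boundary_at_midpoint(self, rng):
        # two 2-D classes with identity covariance, means (0,0) and (4,0):
        # the discriminant boundary is the line x=2
        a = rng.standard_normal((200, 2))
        b = rng.standard_normal((200, 2)) + [4.0, 0.0]
        model = fit_qdc(ScoreMatrix(np.vstack([a, b]), ["c1"] * 200 + ["c2"] * 200))
        assert predict(model, np.array([1.0, 0.0]))[0] == "c1"
        assert predict(model, np.array([3.0, 0.0]))[0] == "c2"
        p_mid = posterior(model, np.array([2.0, 0.0]))
        assert p_mid[0] == pytest.approx(0.5, abs=0.1)

    def test_identical_distributions_posteriors_near_priors(self, rng):
        shared = rng.standard_normal((100, 2))
        model = fit_qdc(ScoreMatrix(np.vstack([shared, shared]), ["a"] * 100 + ["b"] * 100))
        p = posterior(model, rng.standard_normal((20, 2)))
        np.testing.assert_allclose(p, 0.5, atol=1e-6)

    def test_singular_class_covariance_survives_ridge(self):
        # collinear points: sample covariance is singular, ridge rescues it
        line = np.column_stack([np.arange(5.0), 2 * np.arange(5.0)])
        other = np.column_stack([np.arange(5.0), -np.arange(5.0)]) + [10.0, 0.0]
        model = fit_qdc(ScoreMatrix(np.vstack([line, other]), ["a"] * 5 + ["b"] * 5))
        for cov in model.covariances:
            assert np.all(np.linalg.eigvalsh(cov) > 0)
        assert np.isfinite(posterior(model, np.array([1.0, 1.0]))).all()

    def test_priors_are_empirical_fractions(self, rng):
        scores = gaussian_scores(rng, {"a": [0, 0], "b": [5, 5]}, 10)
        extra = ScoreMatrix(
            np.vstack([scores.scores, rng.standard_normal((10, 2)) + 5]),
            list(scores.classes()) + ["b"] * 10,
        )
        model = fit_qdc(extra)
        np.testing.assert_allclose(model.priors, [10 / 30, 20 / 30])

    def test_class_with_one_member_rejected(self, rng):
        with pytest.raises(ValueError, match="fewer than two"):
            fit_qdc(ScoreMatrix(rng.standard_normal((3, 2)), ["a", "a", "b"]))


class TestPosterior:
    def test_at_class_mean_exceeds_half(self, rng):
        scores = gaussian_scores(rng, {"a": [0, 0], "b": [3, 0]}, 50)
        model = fit_qdc(scores)
        assert posterior(model, np.array([0.0, 0.0]))[0] > 0.5

    def test_matches_density_ratio_oracle(self, rng):
        from scipy.stats import multivariate_normal

        scores = gaussian_scores(rng, {"a": [0, 0, 0], "b": [2, 1, 0], "c": [0, 3, 1]}, 30)
        model = fit_qdc(scores)
        x = rng.standard_normal(3)
        dens = np.array(
            [
                pi * multivariate_normal.pdf(x, mean=mu, cov=cov)
                for pi, mu, cov in zip(model.priors, model.means, model.covariances)
            ]
        )
        np.testing.assert_allclose(posterior(model, x), dens / dens.sum(), atol=1e-10)

    def test_matches_sklearn_qda(self, rng):
        qda_mod = pytest.importorskip("sklearn.discriminant_analysis")
        scores = gaussian_scores(rng, {"a": [0, 0], "b": [2, 1]}, 40)
        model = fit_qdc(scores, gamma_scale=0.0)
        ref = qda_mod.QuadraticDiscriminantAnalysis(store_covariance=True).fit(
            scores.scores, scores.classes()
        )
        x = rng.standard_normal((10, 2))
        np.testing.assert_allclose(posterior(model, x), ref.predict_proba(x), atol=1e-8)

    def test_rows_sum_to_one(self, rng):
        scores = gaussian_scores(rng, {"a": [0, 0], "b": [8, 0]}, 20)
        model = fit_qdc(scores)
        p = posterior(model, rng.standard_normal((50, 2)) * 20)  # far tails, needs log-sum-exp
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert np.isfinite(p).all()


class TestFolds:
    def test_two_classes_of_five_give_one_each_per_fold(self):
        y = np.array(["a"] * 5 + ["b"] * 5)
        folds = make_folds(y, n_folds=5, seed=0)
        for f in range(1, 6):
            held = y[folds == f]
            assert sorted(held) == ["a", "b"]

    def test_same_seed_reproduces_assignment(self, rng):
        y = rng.choice(["a", "b", "c"], size=40)
        np.testing.assert_array_equal(make_folds(y, seed=3), make_folds(y, seed=3))

    def test_per_class_fold_sizes_differ_by_at_most_one(self, rng):
        y = np.array(["a"] * 13 + ["b"] * 7)
        folds = make_folds(y, n_folds=5, seed=1)
        for name in "ab":
            sizes = [np.sum((folds == f) & (y == name)) for f in range(1, 6)]
            assert max(sizes) - min(sizes) <= 1

    def test_small_class_reduces_fold_count_with_warning(self):
        y = np.array(["a"] * 3 + ["b"] * 10)
        with pytest.warns(UserWarning, match="reducing folds"):
            folds = make_folds(y, n_folds=5, seed=0)
        assert folds.max() == 3


class TestCrossval:
    def test_every_row_held_out_exactly_once(self, rng):
        scores = gaussian_scores(rng, {"a": [0, 0], "b": [1, 0]}, 12)
        cv = crossval_fivefold(scores, seed=0)
        assert np.isfinite(cv.held_out_posteriors).all()
        np.testing.assert_allclose(cv.held_out_posteriors.sum(axis=1), 1.0, atol=1e-10)

    def test_well_separated_classes_classified_near_perfectly(self, rng):
        # separation 10 sigma, n=50 per class
        scores = gaussian_scores(rng, {"a": [0, 0], "b": [10, 0]}, 50)
        cv = crossval_fivefold(scores, seed=0)
        predicted = np.array(cv.classes)[cv.held_out_posteriors.argmax(axis=1)]
        assert (predicted == cv.y).mean() > 0.98

    def test_determinism(self, rng):
        scores = gaussian_scores(rng, {"a": [0, 0], "b": [2, 0]}, 20)
        a = crossval_fivefold(scores, seed=5)
        b = crossval_fivefold(scores, seed=5)
        np.testing.assert_array_equal(a.fold_assignments, b.fold_assignments)
        np.testing.assert_array_equal(a.held_out_posteriors, b.held_out_posteriors)


class TestROC:
    def test_perfect_separation(self):
        cv = cv_from_binary_scores([0.9, 0.8], [0.1, 0.2])
        assert roc_auc(cv, "pos").auc == 1.0

    def test_ties_get_half_credit(self):
        cv = cv_from_binary_scores([0.8, 0.2], [0.8, 0.4])
        assert roc_auc(cv, "pos").auc == 0.375  # 4 pairs: 1 win, 1 tie, 2 losses

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_concordance_oracle_exactly(self, seed):
        r = np.random.default_rng(seed)
        n_pos, n_neg = r.integers(2, 26, size=2)
        pos = np.round(r.uniform(0, 1, n_pos), 2)  # rounding forces ties
        neg = np.round(r.uniform(0, 1, n_neg), 2)
        cv = cv_from_binary_scores(pos, neg)
        assert roc_auc(cv, "pos").auc == pytest.approx(concordance_auc(pos, neg), abs=1e-12)

    def test_matches_sklearn(self, rng):
        metrics = pytest.importorskip("sklearn.metrics")
        pos, neg = rng.uniform(0, 1, 30), rng.uniform(0, 1, 25)
        cv = cv_from_binary_scores(pos, neg)
        y = np.concatenate([np.ones(30), np.zeros(25)])
        s = np.concatenate([pos, neg])
        assert roc_auc(cv, "pos").auc == pytest.approx(
            metrics.roc_auc_score(y, s), abs=1e-12
        )

    def test_label_swap_antisymmetry(self, rng):
        pos, neg = rng.uniform(0, 1, 15), rng.uniform(0, 1, 20)
        auc = roc_auc(cv_from_binary_scores(pos, neg), "pos").auc
        # swapping which group is called positive, same scores
        swapped = roc_auc(cv_from_binary_scores(neg, pos), "pos").auc
        assert swapped == pytest.approx(1 - auc, abs=1e-12)

    def test_complementary_posterior_gives_equal_class_aucs(self, rng):
        # scoring each class by its own posterior: binary AUCs coincide
        pos, neg = rng.uniform(0, 1, 15), rng.uniform(0, 1, 20)
        cv = cv_from_binary_scores(pos, neg)
        assert roc_auc(cv, "neg").auc == pytest.approx(roc_auc(cv, "pos").auc, abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        cv = cv_from_binary_scores(rng.uniform(0, 1, 20), rng.uniform(0, 1, 20))
        r = roc_auc(cv, "pos")
        assert (r.tpr[0], r.fpr[0]) == (0.0, 0.0)
        assert (r.tpr[-1], r.fpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.tpr) >= 0) and np.all(np.diff(r.fpr) >= 0)

    def test_increasing_transform_leaves_auc_unchanged(self, rng):
        pos, neg = rng.uniform(0, 1, 15), rng.uniform(0, 1, 15)
        a = roc_auc(cv_from_binary_scores(pos, neg), "pos").auc
        b = roc_auc(cv_from_binary_scores(np.exp(3 * pos), np.exp(3 * neg)), "pos").auc
        assert a == pytest.approx(b, abs=1e-12)


class TestMulticlassAUC:
    def test_binary_one_vs_rest_aucs_coincide(self, rng):
        scores = gaussian_scores(rng, {"a": [0, 0], "b": [2, 0]}, 20)
        cv = crossval_fivefold(scores, seed=0)
        res = multiclass_auc(cv)
        assert res[0].auc == pytest.approx(res[1].auc, abs=1e-12)

    def test_four_separated_classes_all_near_one(self, rng):
        means = {"a": [0, 0], "b": [10, 0], "c": [0, 10], "d": [10, 10]}
        cv = crossval_fivefold(gaussian_scores(rng, means, 30), seed=0)
        for r in multiclass_auc(cv):
            assert r.auc > 0.99

    def test_identical_classes_hover_at_chance(self):
        aucs = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            means = {name: [0, 0] for name in "abcd"}
            cv = crossval_fivefold(gaussian_scores(r, means, 25), seed=seed)
            aucs.extend(res.auc for res in multiclass_auc(cv))
        assert abs(np.mean(aucs) - 0.5) < 0.1


class TestDecisionBoundaryGrid:
    def test_symmetric_model_boundary_at_midline(self, rng):
        a = rng.standard_normal((300, 2))
        model = fit_qdc(
            ScoreMatrix(np.vstack([a, a + [6, 0]]), ["l"] * 300 + ["r"] * 300)
        )
        x_axis, y_axis, labels = decision_boundary_grid(model, (-3, 9, -3, 3), (61, 11))
        left = labels[:, x_axis < 2.4]
        right = labels[:, x_axis > 3.6]
        assert (left == "l").mean() > 0.95
        assert (right == "r").mean() > 0.95

    def test_equal_covariance_matches_analytic_linear_boundary(self):
        # exact shared covariance: build classes with identical sample spread
        base = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        model = fit_qdc(
            ScoreMatrix(
                np.vstack([base, base + [4.0, 0.0]]), ["a"] * 4 + ["b"] * 4
            )
        )
        # equal covariances and priors: boundary is the perpendicular
        # bisector x = 2 of the segment between the means
        _, _, labels = decision_boundary_grid(model, (0, 4, -1, 1), (41, 5))
        xs = np.linspace(0, 4, 41)
        for j, x in enumerate(xs):
            expected = "a" if x < 2 else ("b" if x > 2 else labels[0, j])
            assert np.all(labels[:, j] == expected)

    def test_single_cell_grid(self, rng):
        scores = gaussian_scores(rng, {"a": [0, 0], "b": [5, 0]}, 10)
        model = fit_qdc(scores)
        _, _, labels = decision_boundary_grid(model, (-1, 1, -1, 1), 1)
        assert labels.shape == (1, 1) and labels[0, 0] == "a"
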