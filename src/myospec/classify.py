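"""Quadratic discriminant classification of PC scores.

Each class k is modeled as a multivariate Gaussian with its own mean
``mu_k``, covariance ``Sigma_k`` and empirical prior ``pi_k``; the
discriminant is

    delta_k(x) = -1/2 ln|Sigma_k| - 1/2 (x-mu_k)^T Sigma_k^-1 (x-mu_k) + ln pi_k

and posteriors are the softmax of the discriminants (computed with
log-sum-exp).  Class covariances get a small ridge ``gamma I`` (gamma
scaled to the covariance trace) because triplicate measurements can be
nearly collinear in score space.

Evaluation follows the study design: stratified fivefold cross-validation,
held-out posteriors pooled into a single ROC per comparison, AUC by
trapezoid over the tie-grouped curve (identical to pairwise concordance
with half credit for ties).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import ScoreMatrix

__all__ = [
    "QDCModel",
    "CVResult",
    "ROCResult",
    "fit_qdc",
    "posterior",
    "log_posterior",
    "make_folds",
    "crossval_fivefold",
    "roc_auc",
    "multiclass_auc",
    "decision_boundary_grid",
]

DEFAULT_GAMMA_SCALE = 1e-8


@dataclass
class QDCModel:
    classes: list[str]
    means: np.ndarray  # K x d
    covariances: np.ndarray  # K x d x d (ridge already added)
    priors: np.ndarray  # K
    regularization: np.ndarray  # per-class ridge actually added

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]


@dataclass
class CVResult:
    """Pooled held-out posteriors from stratified k-fold cross-validation."""

    classes: list[str]
    y: np.ndarray  # per-measurement true class label
    fold_assignments: np.ndarray  # per-measurement fold index, 1-based
    held_out_posteriors: np.ndarray  # n x K, each row from the fold that held it out
    seed: int
    n_folds: int


@dataclass
class ROCResult:
    class_name: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _classes_of(scores: ScoreMatrix, class_field: str | None) -> np.ndarray:
    return scores.classes(class_field)


def fit_qdc(
    scores: ScoreMatrix,
    class_field: str | None = None,
    *,
    gamma_scale: float = DEFAULT_GAMMA_SCALE,
) -> QDCModel:
    """Fit per-class Gaussians: sample mean, sample covariance (n_k - 1
    denominator) plus ridge ``gamma_scale * trace(Sigma_k)/d`` on the
    diagonal, and empirical priors ``n_k / n``."""
    x = scores.scores
    y = _classes_of(scores, class_field)
    if not np.all(np.isfinite(x)):
        raise ValueError("scores contain non-finite values")
    class_names = sorted(set(y))
    if len(class_names) < 2:
        raise ValueError("classification needs at least two classes")

    d = x.shape[1]
    means, covs, priors, gammas = [], [], [], []
    for name in class_names:
        xk = x[y == name]
        if xk.shape[0] < 2:
            raise ValueError(f"class {name!r} has fewer than two members")
        mu = xk.mean(axis=0)
        sigma = np.cov(xk, rowvar=False, ddof=1).reshape(d, d)
        trace = float(np.trace(sigma))
        gamma = gamma_scale * (trace / d if trace > 0 else 1.0)
        means.append(mu)
        covs.append(sigma + gamma * np.eye(d))
        priors.append(xk.shape[0] / x.shape[0])
        gammas.append(gamma)

    return QDCModel(
        classes=class_names,
        means=np.asarray(means),
        covariances=np.asarray(covs),
        priors=np.asarray(priors),
        regularization=np.asarray(gammas),
    )


def _discriminants(model: QDCModel, x: np.ndarray) -> np.ndarray:
    """delta_k(x) for each row of x; returns n x K."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_dims:
        raise ValueError(f"expected {model.n_dims}-dimensional scores, got {x.shape[1]}")
    if not np.all(np.isfinite(x)):
        raise ValueError("scores contain non-finite values")
    out = np.empty((x.shape[0], model.n_classes))
    for k in range(model.n_classes):
        sigma = model.covariances[k]
        sign, logdet = np.linalg.slogdet(sigma)
        if sign <= 0:
            raise np.linalg.LinAlgError("class covariance not positive-definite")
        diff = x - model.means[k]
        mahal = np.einsum("ij,ij->i", diff, np.linalg.solve(sigma, diff.T).T)
        out[:, k] = -0.5 * logdet - 0.5 * mahal + np.log(model.priors[k])
    return out


def log_posterior(model: QDCModel, x: np.ndarray) -> np.ndarray:
    delta = _discriminants(model, x)
    shifted = delta - delta.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def posterior(model: QDCModel, x: np.ndarray) -> np.ndarray:
    """Per-class posterior probabilities (rows sum to one)."""
    single = np.asarray(x).ndim == 1
    p = np.exp(log_posterior(model, x))
    return p[0] if single else p


def predict(model: QDCModel, x: np.ndarray) -> np.ndarray:
    p = np.atleast_2d(posterior(model, x))
    return np.array([model.classes[i] for i in p.argmax(axis=1)])


def make_folds(y: np.ndarray, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment, 1-based.

    Rows of each class are shuffled by a seeded permutation and dealt
    round-robin into folds, so per-class fold sizes differ by at most one.
    If the smallest class has fewer members than ``n_folds`` the fold count
    is reduced to that size (with a warning).
    """
    y = np.asarray(y)
    counts = {name: int((y == name).sum()) for name in sorted(set(y))}
    smallest = min(counts.values())
    if smallest < 2:
        raise ValueError("every class needs at least two members for cross-validation")
    if smallest < n_folds:
        warnings.warn(
            f"smallest class has {smallest} members; reducing folds from "
            f"{n_folds} to {smallest}",
            stacklevel=2,
        )
        n_folds = smallest

    rng = np.random.default_rng(seed)
    folds = np.empty(len(y), dtype=int)
    for name in sorted(counts):
        idx = np.flatnonzero(y == name)
        perm = rng.permutation(len(idx))
        folds[idx[perm]] = np.arange(len(idx)) % n_folds + 1
    return folds


def crossval_fivefold(
    scores: ScoreMatrix,
    class_field: str | None = None,
    seed: int = 0,
    n_folds: int = 5,
    *,
    gamma_scale: float = DEFAULT_GAMMA_SCALE,
) -> CVResult:
    """Stratified k-fold CV of the QDC; held-out posteriors pooled.

    For each fold the classifier is fit on the other folds and posteriors
    are recorded for the held-out rows only, so every measurement gets
    exactly one out-of-sample posterior vector.
    """
    y = _classes_of(scores, class_field)
    folds = make_folds(y, n_folds=n_folds, seed=seed)
    actual_folds = int(folds.max())
    class_names = sorted(set(y))
    post = np.full((len(y), len(class_names)), np.nan)
    for f in range(1, actual_folds + 1):
        test = folds == f
        train = ~test
        model = fit_qdc(
            ScoreMatrix(scores.scores[train], list(y[train])), gamma_scale=gamma_scale
        )
        p = np.atleast_2d(posterior(model, scores.scores[test]))
        # map model class order onto the global class order
        order = [model.classes.index(name) for name in class_names]
        post[test] = p[:, order]
    return CVResult(
        classes=class_names,
        y=y,
        fold_assignments=folds,
        held_out_posteriors=post,
        seed=seed,
        n_folds=actual_folds,
    )


def _roc_from_scores(score: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both positive and negative examples")

    order = np.argsort(-score, kind="stable")
    s, p = score[order], positive[order]
    # group tied scores so the curve moves diagonally through ties
    boundaries = np.flatnonzero(np.diff(s) != 0)
    ends = np.concatenate([boundaries, [len(s) - 1]])
    tp = np.cumsum(p)[ends]
    fp = np.cumsum(~p)[ends]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], s[ends]])
    auc = float(np.trapezoid(tpr, fpr))
    return thresholds, tpr, fpr, auc


def roc_auc(cv: CVResult, positive_class: str) -> ROCResult:
    """One-vs-rest ROC from pooled held-out posteriors of ``positive_class``.

    The trapezoidal AUC over the tie-grouped curve equals the pairwise
    concordance ``P(s+ > s-) + 1/2 P(s+ = s-)``.
    """
    if positive_class not in cv.classes:
        raise ValueError(f"unknown class {positive_class!r}")
    k = cv.classes.index(positive_class)
    score = cv.held_out_posteriors[:, k]
    positive = cv.y == positive_class
    thresholds, tpr, fpr, auc = _roc_from_scores(score, positive)
    return ROCResult(class_name=positive_class, thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def multiclass_auc(cv: CVResult) -> list[ROCResult]:
    """One ROC per class, one-vs-rest, each scored by that class's posterior."""
    return [roc_auc(cv, name) for name in cv.classes]


def decision_boundary_grid(
    model: QDCModel,
    bounds: tuple[float, float, float, float],
    resolution: int | tuple[int, int] = 200,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted class label on a 2-D grid, for score-space plots.

    For models with more than two score dimensions the remaining
    coordinates are fixed at zero (the training-score mean).  Returns
    ``(x_axis, y_axis, labels)`` with ``labels[i, j]`` the prediction at
    ``(x_axis[j], y_axis[i])``.
    """
    xmin, xmax, ymin, ymax = bounds
    if not (xmin < xmax and ymin < ymax):
        raise ValueError("degenerate bounds")
    nx, ny = (resolution, resolution) if isinstance(resolution, int) else resolution
    if nx < 1 or ny < 1:
        raise ValueError("resolution must be positive")
    x_axis = np.linspace(xmin, xmax, nx)
    y_axis = np.linspace(ymin, ymax, ny)
    xx, yy = np.meshgrid(x_axis, y_axis)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    if model.n_dims > 2:
        pts = np.column_stack([pts, np.zeros((pts.shape[0], model.n_dims - 2))])
    labels = predict(model, pts).reshape(ny, nx)
    return x_axis, y_axis, labels
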