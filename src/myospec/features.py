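"""Principal-component feature extraction for spectral matrices.

Spectra are highly collinear across wavelengths, so a handful of principal
components captures nearly all between-measurement variance.  PCA here is
covariance-PCA (mean-centering only, no per-wavelength scaling: normalized
spectra are already on a common scale) computed by singular-value
decomposition of the centered matrix.  The first three components are
retained by default and each observation is projected to a three-variable
score vector for classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .spectra import MeasurementRecord

__all__ = ["PCAModel", "ScoreMatrix", "fit_pca", "project", "cumulative_variance"]


@dataclass
class PCAModel:
    """Mean spectrum, unit-norm loading vectors, and variance fractions.

    ``explained_variance_fraction`` is the retained components' share of
    the *total* variance (all possible components), so the fractions of a
    full-rank fit sum to one.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # n_components x n_wavelengths
    explained_variance_fraction: np.ndarray
    explained_variance: np.ndarray  # per-component variance (n-1 denominator)
    total_variance: float
    n_samples: int

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_wavelengths(self) -> int:
        return self.loadings.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean_spectrum": self.mean_spectrum.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "total_variance": self.total_variance,
            "n_samples": self.n_samples,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            mean_spectrum=np.asarray(d["mean_spectrum"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance_fraction=np.asarray(d["explained_variance_fraction"], dtype=float),
            explained_variance=np.asarray(d["explained_variance"], dtype=float),
            total_variance=float(d["total_variance"]),
            n_samples=int(d["n_samples"]),
        )


@dataclass
class ScoreMatrix:
    """Projected observations: n_measurements x n_components scores.

    ``labels`` may be full measurement records (classes picked out later by
    a class field) or plain per-row class strings for synthetic studies.
    """

    scores: np.ndarray
    labels: Sequence[MeasurementRecord | str] = field(default_factory=list)
    class_field: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if len(self.labels) and len(self.labels) != self.scores.shape[0]:
            raise ValueError("labels length does not match score rows")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def classes(self, class_field: str | None = None) -> np.ndarray:
        field_name = class_field or self.class_field
        out = []
        for label in self.labels:
            if isinstance(label, MeasurementRecord):
                if field_name is None:
                    raise ValueError("class_field required to read record labels")
                out.append(label.label(field_name))
            else:
                out.append(str(label))
        return np.array(out)


def fit_pca(matrix: np.ndarray, n_components: int = 3) -> PCAModel:
    """Fit covariance-PCA by SVD of the mean-centered matrix.

    Components are ordered by decreasing variance.  Sign convention: the
    largest-magnitude coefficient of each loading is made positive, so
    models are reproducible across linear-algebra backends.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("matrix must be 2-D (measurements x wavelengths)")
    n, p = x.shape
    if n < 2:
        raise ValueError("PCA needs at least two measurements")
    max_rank = min(n - 1, p)
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}] for a {n}x{p} matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix contains non-finite values")

    mean = x.mean(axis=0)
    centered = x - mean
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    variances = s**2 / (n - 1)
    total = float(variances.sum())
    if total <= 0:
        raise ValueError("matrix has zero variance; PCA undefined")

    loadings = vt[:n_components]
    # fix signs: largest-|coefficient| entry of each loading made positive
    flip = np.sign(loadings[np.arange(n_components), np.argmax(np.abs(loadings), axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]

    return PCAModel(
        mean_spectrum=mean,
        loadings=loadings,
        explained_variance_fraction=variances[:n_components] / total,
        explained_variance=variances[:n_components],
        total_variance=total,
        n_samples=n,
    )


def project(
    model: PCAModel,
    matrix: np.ndarray,
    labels: Sequence[MeasurementRecord | str] = (),
    class_field: str | None = None,
) -> ScoreMatrix:
    """Scores = (matrix - mean) @ loadings.T."""
    x = np.atleast_2d(np.asarray(matrix, dtype=float))
    if x.shape[1] != model.n_wavelengths:
        raise ValueError(
            f"matrix has {x.shape[1]} wavelengths but model expects {model.n_wavelengths}"
        )
    scores = (x - model.mean_spectrum) @ model.loadings.T
    return ScoreMatrix(scores=scores, labels=list(labels), class_field=class_field)


def cumulative_variance(model: PCAModel, k: int) -> float:
    """Fraction of total variance explained by the first ``k`` components."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > model.n_components:
        raise ValueError(f"model has only {model.n_components} components")
    return float(model.explained_variance_fraction[:k].sum())
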