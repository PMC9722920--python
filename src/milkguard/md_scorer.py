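"""Squared Mahalanobis-distance anomaly scoring with F1-optimal cutoff.

The reference (presumed-normal) population defines a centroid μ and sample
covariance Σ; a query x is scored by the squared Mahalanobis distance

    MD²(x) = (x − μ)ᵀ (Σ + λI)⁻¹ (x − μ),

with a small ridge λ (default 1e-8·trace(Σ)/p) keeping the metric defined
when Σ is singular or ill-conditioned. Samples scoring strictly above a
cutoff are flagged as spiked; the cutoff is chosen by scanning a score grid
and keeping the value with the highest F1 (spiked = positive class),
breaking ties toward the smallest cutoff.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class MDModel:
    """Centroid, regularized precision matrix and optional decision cutoff."""

    centroid: np.ndarray
    precision: np.ndarray
    feature_names: tuple[str, ...] | None = None
    cutoff: float | None = None
    regularization: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroid)):
            raise ValueError("centroid must be finite")
        if not np.allclose(self.precision, self.precision.T, atol=1e-10):
            raise ValueError("precision matrix must be symmetric")
        if self.cutoff is not None and self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "centroid": self.centroid.tolist(),
            "precision": self.precision.tolist(),
            "feature_names": list(self.feature_names) if self.feature_names else None,
            "cutoff": self.cutoff,
            "regularization": self.regularization,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MDModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            centroid=np.asarray(payload["centroid"], float),
            precision=np.asarray(payload["precision"], float),
            feature_names=(tuple(payload["feature_names"])
                           if payload["feature_names"] else None),
            cutoff=payload["cutoff"],
            regularization=payload["regularization"],
        )


@dataclass
class CutoffSearchResult:
    """The selected cutoff with the F1 it achieves and the full search curve."""

    cutoff: float
    f1_at_cutoff: float
    grid: np.ndarray
    f1_curve: np.ndarray


def fit_md(reference: np.ndarray,
           feature_names: tuple[str, ...] | None = None,
           regularization: float | None = None) -> MDModel:
    """Fit centroid and regularized precision on a reference matrix.

    ``regularization`` is the ridge λ added to the covariance diagonal;
    ``None`` selects the default 1e-8·trace(Σ)/p. Passing λ=0 with a
    singular Σ raises with instructions to regularize. With fewer reference
    rows than features the covariance is always singular, so a positive λ
    is mandatory there.
    """
    X = np.asarray(reference, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("reference must be a 2-D matrix with >= 2 rows")
    p = X.shape[1]
    centroid = X.mean(axis=0)
    sigma = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    if regularization is None:
        regularization = 1e-8 * np.trace(sigma) / p
        if regularization == 0.0:  # degenerate all-identical reference
            regularization = 1e-8
    if regularization == 0.0:
        # require well-posedness explicitly
        if np.linalg.matrix_rank(sigma) < p:
            raise np.linalg.LinAlgError(
                "sample covariance is singular; pass a positive "
                "regularization (ridge) value")
        precision = np.linalg.inv(sigma)
    else:
        precision = np.linalg.inv(sigma + regularization * np.eye(p))
    precision = (precision + precision.T) / 2.0  # enforce exact symmetry
    return MDModel(centroid=centroid, precision=precision,
                   feature_names=feature_names, regularization=regularization)


def score_md(model: MDModel, x: np.ndarray) -> np.ndarray | float:
    """Squared Mahalanobis distance of one vector or each row of a matrix."""
    x = np.asarray(x, float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.centroid.size:
        raise ValueError(
            f"feature dimension {X.shape[1]} != model dimension "
            f"{model.centroid.size}")
    d = X - model.centroid
    scores = np.einsum("ij,jk,ik->i", d, model.precision, d)
    scores = np.maximum(scores, 0.0)  # guard tiny negative round-off
    return float(scores[0]) if single else scores


def default_cutoff_grid(scores: np.ndarray, n: int = 200) -> np.ndarray:
    """200 even cutoffs from 0 to the 99.9th percentile of training scores."""
    hi = float(np.percentile(scores, 99.9))
    if hi <= 0:
        hi = 1.0
    return np.linspace(0.0, hi, n)


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def select_cutoff(scores: np.ndarray, labels: np.ndarray,
                  grid: np.ndarray | None = None) -> CutoffSearchResult:
    """Scan cutoffs and keep the one maximizing F1 (spiked positive).

    ``labels`` may be the strings ``normal``/``spiked`` or 0/1. A sample is
    classified spiked iff its score is strictly greater than the cutoff.
    Ties on F1 break toward the smallest cutoff. Raises if only one class
    is present (F1-based selection is undefined then).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UO":
        y = (labels == "spiked").astype(int)
    else:
        y = labels.astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to select a cutoff")
    if grid is None:
        grid = default_cutoff_grid(scores)
    grid = np.asarray(grid, float)
    f1s = np.array([_f1(y, (scores > c).astype(int)) for c in grid])
    best = int(np.argmax(f1s))  # argmax returns first max -> smallest cutoff
    return CutoffSearchResult(cutoff=float(grid[best]),
                              f1_at_cutoff=float(f1s[best]),
                              grid=grid, f1_curve=f1s)


def flag(model: MDModel, X: np.ndarray) -> np.ndarray:
    """Binary verdicts (1 = spiked) using the model's stored cutoff."""
    if model.cutoff is None:
        raise ValueError("model has no cutoff; run select_cutoff first")
    scores = np.atleast_1d(score_md(model, X))
    return (scores > model.cutoff).astype(int)
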