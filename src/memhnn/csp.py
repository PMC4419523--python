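"""Common spatial patterns (CSP) for one binary class pair.

CSP finds spatial filters w maximising the variance ratio between two
classes of multichannel trials.  With trace-normalised average covariances
C1 and C2, the filters solve the generalized eigenproblem::

    C1 w = λ (C1 + C2) w,      λ ∈ (0, 1)

Eigenvectors with λ near 1 concentrate class-1 variance, those with λ near
0 concentrate class-2 variance; the model keeps the extremes from both
ends.  Features are log band-power ratios of the spatially filtered trial,
and the binarization thresholds are the training-set medians of each
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import eigh

__all__ = ["CSPModel", "csp_fit", "csp_features", "spatial_covariance", "bit_thresholds"]


def bit_thresholds(features: np.ndarray, method: str = "cluster") -> np.ndarray:
    """Per-feature binarization cutoffs from training-set feature values.

    ``method="cluster"`` (default) runs a one-dimensional 2-means on each
    feature and returns the midpoint of the two cluster centres.  With
    three classes, a pairwise CSP feature is typically bimodal with a 1:2
    class split, so the cluster midpoint separates the modes where a plain
    median would cut through the thicker mode and randomise the bit.
    ``method="median"`` returns the classical training-set median.
    """
    F = np.asarray(features, dtype=float)
    if F.ndim != 2:
        raise ValueError("features must be (n_samples, n_features)")
    if method == "median":
        return np.median(F, axis=0)
    if method != "cluster":
        raise ValueError(f"unknown threshold method {method!r}")
    out = np.empty(F.shape[1])
    for j, col in enumerate(F.T):
        c1, c2 = np.percentile(col, [10, 90])
        if c1 == c2:
            out[j] = c1
            continue
        for _ in range(100):
            mid = 0.5 * (c1 + c2)
            low, high = col[col <= mid], col[col > mid]
            n1 = low.mean() if low.size else c1
            n2 = high.mean() if high.size else c2
            if n1 == c1 and n2 == c2:
                break
            c1, c2 = n1, n2
        out[j] = 0.5 * (c1 + c2)
    return out


def spatial_covariance(trial: np.ndarray) -> np.ndarray:
    """Trace-normalised spatial covariance of one (channels x samples) trial."""
    x = np.asarray(trial, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    c = x @ x.T
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("zero-variance trial")
    return c / tr


@dataclass
class CSPModel:
    """Fitted spatial filters for one class pair.

    filters : (n_filters x channels) matrix, rows ordered from the most
        class-1-selective (largest λ) to the most class-2-selective.
    eigenvalues : λ of each retained filter, in (0, 1).
    class_pair : the (class1, class2) labels the model discriminates.
    feature_thresholds : per-feature training-set medians used by the
        binarizer; None until fitted via :meth:`fit_thresholds`.
    """

    filters: np.ndarray
    eigenvalues: np.ndarray
    class_pair: Tuple[str, str]
    feature_thresholds: Optional[np.ndarray] = None

    @property
    def n_filters(self) -> int:
        return self.filters.shape[0]

    def fit_thresholds(
        self, training_trials: Sequence[np.ndarray], method: str = "cluster"
    ) -> "CSPModel":
        feats = np.stack([csp_features(self, t) for t in training_trials])
        self.feature_thresholds = bit_thresholds(feats, method=method)
        return self


def csp_fit(
    trials_class1: Sequence[np.ndarray],
    trials_class2: Sequence[np.ndarray],
    n_filters: int = 10,
    class_pair: Tuple[str, str] = ("a", "i"),
    reg: float = 1e-6,
    shrinkage: float = 0.0,
) -> CSPModel:
    """Fit CSP filters from two sets of (channels x samples) trials.

    Keeps the ``n_filters/2`` largest-λ and smallest-λ eigenvectors.
    ``shrinkage`` blends each class covariance with a trace-scaled identity
    (small-sample stabilisation); independently of that, when the composite
    covariance is near-singular a trace-scaled ridge ``reg`` is added
    before solving.
    """
    if len(trials_class1) < 2 or len(trials_class2) < 2:
        raise ValueError("need at least 2 trials per class")
    if n_filters % 2:
        raise ValueError("n_filters must be even")
    if not 0.0 <= shrinkage < 1.0:
        raise ValueError("shrinkage must lie in [0, 1)")
    c1 = np.mean([spatial_covariance(t) for t in trials_class1], axis=0)
    c2 = np.mean([spatial_covariance(t) for t in trials_class2], axis=0)
    n_ch = c1.shape[0]
    if shrinkage > 0:
        eye = np.eye(n_ch)
        c1 = (1 - shrinkage) * c1 + shrinkage * (np.trace(c1) / n_ch) * eye
        c2 = (1 - shrinkage) * c2 + shrinkage * (np.trace(c2) / n_ch) * eye
    if n_filters > n_ch:
        raise ValueError(f"n_filters = {n_filters} exceeds {n_ch} channels")
    comp = c1 + c2
    if np.linalg.cond(comp) > 1e12:
        comp = comp + reg * (np.trace(comp) / n_ch) * np.eye(n_ch)
    evals, evecs = eigh(c1, comp)  # ascending λ, B-orthonormal vectors
    k = n_filters // 2
    order = np.concatenate([np.arange(n_ch - 1, n_ch - k - 1, -1), np.arange(k - 1, -1, -1)])
    return CSPModel(
        filters=evecs[:, order].T.copy(),
        eigenvalues=evals[order].copy(),
        class_pair=tuple(class_pair),
    )


def csp_features(model: CSPModel, trial: np.ndarray) -> np.ndarray:
    """Normalised log-variance features of one trial under the model's filters."""
    x = np.asarray(trial, dtype=float)
    if x.shape[0] != model.filters.shape[1]:
        raise ValueError("channel count does not match the fitted model")
    x = x - x.mean(axis=1, keepdims=True)
    z = model.filters @ x
    var = z.var(axis=1)
    total = var.sum()
    if total <= 0:
        raise ValueError("zero-variance trial")
    return np.log(var / total)
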