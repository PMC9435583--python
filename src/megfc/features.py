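"""Edge-feature extraction and F-score ranking of connectivity matrices.

A symmetric p x p functional-connectivity (FC) matrix is flattened to its
lower triangle plus main diagonal, giving m = p(p-1)/2 + p features per
segment (m = 2,775 for the 74-parcel cortical grid).  Features are ranked
by the two-class F-score

    F_i = [ (mean_i^- - mean_i)^2 + (mean_i^+ - mean_i)^2 ]
          / [ s2_i^+ + s2_i^- ]

where ``mean_i`` is the pooled mean of feature i, ``mean_i^+/-`` the class
means, and ``s2_i^+/-`` the unbiased (n-1 denominator) within-class sample
variances.  A larger F-score means a stronger univariate separation between
the two classes.  The top fraction (1% by default) of features feeds the
downstream SVM.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted, validate_data

__all__ = [
    "n_features",
    "feature_index_map",
    "vectorize_fc",
    "devectorize_fc",
    "f_score",
    "select_top_fraction",
    "FScoreSelector",
]


def n_features(n_parcels: int) -> int:
    """Length of the edge-feature vector for ``n_parcels`` regions."""
    return n_parcels * (n_parcels + 1) // 2


def feature_index_map(n_parcels: int) -> np.ndarray:
    """Canonical feature-index -> (parcel_i, parcel_j) map, i >= j.

    Features traverse the lower triangle (diagonal included) row-major:
    rows i = 0..p-1, columns j = 0..i.  Returns an (m, 2) integer array.
    """
    rows, cols = np.tril_indices(n_parcels)
    return np.column_stack([rows, cols])


def edge_to_feature_index(i: int, j: int) -> int:
    """Feature index of the undirected edge (i, j) under the canonical map."""
    r, c = (i, j) if i >= j else (j, i)
    return r * (r + 1) // 2 + c


def vectorize_fc(fc: np.ndarray, *, atol: float = 1e-8) -> np.ndarray:
    """Flatten a symmetric FC matrix into the canonical feature vector.

    Parameters
    ----------
    fc : (p, p) array, symmetric within ``atol``.

    Returns
    -------
    (m,) vector of the lower triangle including the main diagonal,
    row-major; m = p(p+1)/2.
    """
    fc = np.asarray(fc)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise ValueError(f"FC matrix must be square, got shape {fc.shape}")
    if not np.allclose(fc, fc.T, atol=atol):
        raise ValueError("FC matrix is asymmetric beyond tolerance")
    rows, cols = np.tril_indices(fc.shape[0])
    return fc[rows, cols]


def devectorize_fc(vec: np.ndarray) -> np.ndarray:
    """Inverse of :func:`vectorize_fc`: rebuild the symmetric matrix."""
    vec = np.asarray(vec)
    m = vec.shape[-1]
    p = int((math.isqrt(8 * m + 1) - 1) // 2)
    if n_features(p) != m:
        raise ValueError(f"length {m} is not a triangular number")
    out = np.zeros((p, p), dtype=vec.dtype)
    rows, cols = np.tril_indices(p)
    out[rows, cols] = vec
    out[cols, rows] = vec
    return out


def f_score(
    X: np.ndarray,
    y: np.ndarray,
    *,
    positive_label=1,
    zero_denominator: str = "zero",
) -> np.ndarray:
    """Two-class F-score of every feature column.

    Parameters
    ----------
    X : (n_samples, n_features)
    y : (n_samples,) with exactly two label values; ``positive_label``
        marks the positive class.
    zero_denominator : {"zero", "inf"}
        Value assigned when the pooled within-class variance is zero
        (constant feature).  ``"zero"`` (default) scores such features 0;
        ``"inf"`` assigns +inf when the class means still differ.

    Each class must contribute at least two samples so that the unbiased
    sample variances exist.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    if zero_denominator not in ("zero", "inf"):
        raise ValueError("zero_denominator must be 'zero' or 'inf'")
    pos = y == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"each class needs >= 2 samples (got {n_pos} positive, {n_neg} negative)"
        )
    if n_pos + n_neg != len(y):
        raise ValueError("y contains labels other than the two classes")

    mean_all = X.mean(axis=0)
    mean_pos = X[pos].mean(axis=0)
    mean_neg = X[~pos].mean(axis=0)
    num = (mean_neg - mean_all) ** 2 + (mean_pos - mean_all) ** 2
    den = X[pos].var(axis=0, ddof=1) + X[~pos].var(axis=0, ddof=1)

    scores = np.zeros_like(num)
    ok = den > 0
    scores[ok] = num[ok] / den[ok]
    if zero_denominator == "inf":
        scores[~ok & (num > 0)] = np.inf
    return scores


def select_top_fraction(scores: np.ndarray, fraction: float = 0.01) -> np.ndarray:
    """Indices of the top ``fraction`` of features by score.

    k = ceil(fraction * m) indices are returned sorted by descending
    score; ties are broken by ascending feature index.
    """
    scores = np.asarray(scores)
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    m = scores.shape[0]
    k = math.ceil(fraction * m)
    # lexsort: primary key last -> sort by -score, then by index for ties
    order = np.lexsort((np.arange(m), -scores))
    return order[:k]


class FScoreSelector(SelectorMixin, BaseEstimator):
    """Select the top-scoring fraction of features by two-class F-score.

    scikit-learn selector: ``fit(X, y)`` computes per-feature F-scores on
    the training samples only; ``transform`` keeps the k = ceil(fraction*m)
    best features (ties resolved toward lower feature index).

    Parameters
    ----------
    fraction : float, default 0.01
        Fraction of features kept.
    positive_label : default 1
        Label treated as the positive class.
    zero_denominator : {"zero", "inf"}, default "zero"
        Convention for constant features (see :func:`f_score`).

    Attributes
    ----------
    scores_ : (n_features,) F-score per feature.
    selected_ : (k,) selected feature indices, descending score.
    """

    def __init__(self, fraction: float = 0.01, positive_label=1,
                 zero_denominator: str = "zero"):
        self.fraction = fraction
        self.positive_label = positive_label
        self.zero_denominator = zero_denominator

    def fit(self, X, y):
        X = validate_data(self, X, ensure_2d=True, dtype=float)
        y = np.asarray(y)
        self.scores_ = f_score(
            X, y,
            positive_label=self.positive_label,
            zero_denominator=self.zero_denominator,
        )
        self.selected_ = select_top_fraction(self.scores_, self.fraction)
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        mask = np.zeros(self.scores_.shape[0], dtype=bool)
        mask[self.selected_] = True
        return mask
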