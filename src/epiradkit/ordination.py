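"""Classical multidimensional scaling of binary methylation-call profiles.

Samples are embedded from their pairwise dissimilarities over the
differentially methylated loci (principal-coordinates analysis): square the
distances, double-center, eigendecompose, and scale eigenvectors by the
square root of their (positive) eigenvalues.  Percent variance per axis is
taken over the positive part of the spectrum only, so percentages stay in
[0, 100] even for non-Euclidean dissimilarities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_array, check_is_fitted

METRICS = ("euclidean", "hamming", "jaccard")


def binary_distance(
    calls: pd.DataFrame, universe, metric: str = "euclidean"
) -> pd.DataFrame:
    """Pairwise sample dissimilarity over the differential-locus universe.

    ``euclidean`` on 0/1 vectors is the square root of the Hamming count —
    the canonical input for classical scaling; ``hamming`` (mismatch
    proportion) and ``jaccard`` are available as alternatives.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    universe = pd.Index(universe)
    if len(universe) == 0:
        raise ValueError("empty locus universe: no distances to compute")
    profiles = calls.loc[universe].T.to_numpy(dtype=float)
    d = squareform(pdist(profiles, metric=metric))
    return pd.DataFrame(d, index=calls.columns, columns=calls.columns)


class ClassicalMDS(BaseEstimator):
    """Principal-coordinates embedding of a precomputed distance matrix.

    Fitted attributes: ``embedding_`` (n_samples x k), ``eigenvalues_`` (full
    spectrum, descending) and ``explained_variance_ratio_`` (fractions of the
    positive-eigenvalue sum for the returned axes).
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y=None):
        D = check_array(X, dtype="numeric")
        n = D.shape[0]
        if D.shape[1] != n:
            raise ValueError("distance matrix must be square")
        if not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(D), 0, atol=1e-8):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(D < -1e-12):
            raise ValueError("distances must be non-negative")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D**2) @ J
        eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
        pos = eigvals > max(eigvals.max(), 0) * 1e-12
        n_pos = int(pos.sum())
        k = min(self.n_components, n_pos)
        if k < self.n_components:
            warnings.warn(
                f"only {n_pos} positive eigenvalues; returning {k} axes",
                stacklevel=2,
            )
        self.eigenvalues_ = eigvals
        self.embedding_ = eigvecs[:, :k] * np.sqrt(eigvals[:k])
        pos_sum = eigvals[pos].sum()
        self.explained_variance_ratio_ = (
            eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
        )
        self.n_features_in_ = n
        return self

    def fit_transform(self, X, y=None):
        return self.fit(X).embedding_

    def transform(self, X):
        check_is_fitted(self, "embedding_")
        raise NotImplementedError(
            "classical MDS embeds the fitted distance matrix only; "
            "use fit_transform"
        )


@dataclass
class MdsResult:
    """Coordinates plus per-axis eigenvalues and percent variance."""

    coordinates: pd.DataFrame  # samples x MDS1..MDSk
    eigenvalues: np.ndarray
    percent_variance: np.ndarray  # per returned axis, of positive spectrum

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def classical_mds(D: pd.DataFrame, n_axes: int = 2) -> MdsResult:
    """Classical scaling of a labelled distance matrix into ``n_axes`` axes."""
    est = ClassicalMDS(n_components=n_axes)
    coords = est.fit_transform(D.to_numpy(dtype=float))
    k = coords.shape[1]
    frame = pd.DataFrame(
        coords, index=D.index, columns=[f"MDS{i+1}" for i in range(k)]
    )
    return MdsResult(
        coordinates=frame,
        eigenvalues=est.eigenvalues_,
        percent_variance=100.0 * est.explained_variance_ratio_,
    )
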