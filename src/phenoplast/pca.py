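"""Centered, unscaled PCA with variable-level diagnostics.

The workflow runs PCA on the centered (but not scaled) protein matrix and
inspects, per principal component: the explained-variance scree, each
protein's cos² (quality of representation), and its signed variable
coordinate (loading × √eigenvalue, equal to the protein-score correlation
times the protein's standard deviation).  The number of retained components
is the smallest count whose cumulative explained variance reaches a
threshold (80% by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .expression_io import CenteredMatrix, PhenoplastError


@dataclass
class PCAModel:
    """SVD-based PCA of a centered matrix, FactoMineR-style diagnostics.

    eigenvalues : variance captured per component, descending (s²/(n−1))
    scores      : n×p sample coordinates (U·s)
    loadings    : p×p orthonormal basis vectors (columns)
    var_coords  : p×p signed variable coordinates, loading·√eigenvalue
    cos2        : p×p quality of representation; rows sum to 1
    """

    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    cum_pct_variance: np.ndarray
    scores: np.ndarray
    loadings: np.ndarray
    var_coords: np.ndarray
    cos2: np.ndarray
    protein_names: list[str]

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def fit_pca(matrix: CenteredMatrix) -> PCAModel:
    """Fit PCA by singular value decomposition of the centered matrix.

    The sign of each loading column is fixed so that its largest-magnitude
    entry is positive — SVD signs are arbitrary, and the feature heuristics
    compare loading signs across proteins, so a deterministic convention is
    required.  Rank-deficient input is allowed (trailing zero eigenvalues).
    Zero-variance proteins get an all-zero cos² row, with a warning.
    """
    X = np.asarray(matrix.values, dtype=float)
    n, p = X.shape
    if n < 2 or p < 2:
        raise PhenoplastError(f"PCA needs n >= 2 and p >= 2, got {n}x{p}")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|entry| of each loading column positive
    flip = np.sign(Vt[np.arange(len(s)), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]

    eigenvalues = s**2 / (n - 1)
    total = eigenvalues.sum()
    if total <= 0:
        raise PhenoplastError("matrix has zero total variance")
    pct = 100.0 * eigenvalues / total
    cum_pct = np.cumsum(pct)
    cum_pct[-1] = 100.0  # guard accumulated round-off at the closure point

    loadings = Vt.T  # p x p (p = min(n-1 might be < p handled below))
    scores = U * s  # n x k
    if loadings.shape[1] < p:  # pad rank-deficient decompositions
        k = loadings.shape[1]
        loadings = np.hstack([loadings, np.zeros((p, p - k))])
        scores = np.hstack([scores, np.zeros((n, p - k))])
        eigenvalues = np.concatenate([eigenvalues, np.zeros(p - k)])
        pct = np.concatenate([pct, np.zeros(p - k)])
        cum_pct = np.concatenate([cum_pct, np.full(p - k, 100.0)])

    var_coords = loadings * np.sqrt(eigenvalues)[None, :]
    row_ss = (var_coords**2).sum(axis=1)
    cos2 = np.zeros_like(var_coords)
    nonzero = row_ss > 0
    cos2[nonzero] = var_coords[nonzero] ** 2 / row_ss[nonzero, None]
    if not nonzero.all():
        dead = [matrix.protein_names[j] for j in np.where(~nonzero)[0]]
        warnings.warn(f"zero-variance proteins, cos2 reported as 0: {dead}")

    return PCAModel(
        eigenvalues=eigenvalues,
        pct_variance=pct,
        cum_pct_variance=cum_pct,
        scores=scores,
        loadings=loadings,
        var_coords=var_coords,
        cos2=cos2,
        protein_names=list(matrix.protein_names),
    )


def significant_dimensions(cum_pct_variance, thresh: float = 80.0) -> int:
    """Smallest component count whose cumulative explained variance >= thresh (%).

    The comparison is inclusive: a cumulative variance exactly at the
    threshold retains that component.
    """
    cum = np.asarray(cum_pct_variance, dtype=float)
    if cum.size == 0:
        raise PhenoplastError("empty cumulative-variance vector")
    if not (0 < thresh <= 100):
        raise PhenoplastError(f"threshold must be in (0, 100], got {thresh}")
    hits = np.where(cum >= thresh)[0]
    if hits.size == 0:
        raise PhenoplastError("cumulative variance never reaches the threshold")
    return int(hits[0]) + 1


def variable_diagnostics(model: PCAModel, ndims: int) -> pd.DataFrame:
    """Long-format per-protein diagnostics for the retained dimensions.

    One row per (protein, dimension) with cos², the signed variable
    coordinate, and its absolute amplitude — the inputs to scree/cos²/
    amplitude plots and to the feature-proposal heuristics.
    """
    if not (1 <= ndims <= model.n_components):
        raise PhenoplastError(f"ndims must be in [1, {model.n_components}]")
    records = []
    for j, name in enumerate(model.protein_names):
        for d in range(ndims):
            records.append(
                {
                    "protein": name,
                    "dimension": d + 1,
                    "cos2": float(model.cos2[j, d]),
                    "var_coord": float(model.var_coords[j, d]),
                    "amplitude": float(abs(model.var_coords[j, d])),
                }
            )
    return pd.DataFrame.from_records(records)
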