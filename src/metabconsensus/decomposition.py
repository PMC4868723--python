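"""Standardization and PCA for the inter-class diversity assessment.

PCA is computed by singular value decomposition of the standardized
matrix; components are ordered by decreasing explained variance and the
sign of each loading vector is fixed by making its largest-magnitude
entry positive (sign indeterminacy otherwise breaks snapshot outputs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DecompositionError(ValueError):
    pass


def standardize(values: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Column-wise z-scores over non-missing entries (population SD, divisor n).

    Missing (NaN) entries are imputed to 0 — the column mean — in the
    returned matrix, which is intended for decomposition and
    centroid-distance computations only.

    Raises
    ------
    DecompositionError
        If a column has fewer than two non-missing values or zero variance
        (the offending metabolite is named when ``names`` is given).
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    n_obs = mask.sum(axis=0)
    bad = np.flatnonzero(n_obs < 2)
    if bad.size:
        label = names[bad[0]] if names else f"column {bad[0]}"
        raise DecompositionError(f"{label}: fewer than 2 non-missing values")
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0)  # divisor n
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        label = names[zero[0]] if names else f"column {zero[0]}"
        raise DecompositionError(f"{label}: zero variance")
    out = (values - mean) / sd
    out[~mask] = 0.0
    return out


@dataclass
class PcaResult:
    """Principal components of a standardized matrix.

    ``scores`` (n × k) are the sample coordinates, ``loadings`` (p × k)
    the orthonormal component directions, ``explained_variance`` the
    non-increasing per-component variances (divisor-n convention, so they
    sum to the total variance of the input over all min(n, p) components).
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    k: int


def pca(values: np.ndarray, k: int) -> PcaResult:
    """Top-``k`` principal components of an already-standardized matrix."""
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n, p):
        raise DecompositionError(f"k={k} outside 1..min(n, p)={min(n, p)}")
    # re-center defensively; standardized input is already centered
    X = X - X.mean(axis=0)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[:k].T
    # sign convention: largest-magnitude entry of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    explained = (s[:k] ** 2) / n
    return PcaResult(scores=X @ loadings, loadings=loadings,
                     explained_variance=explained, k=k)
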