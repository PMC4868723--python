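"""Sparse PLS discriminant analysis by penalized rank-1 decomposition.

For each component ``h`` the cross-product matrix ``M_h = X_hᵀ Y_h`` of
the (standardized) feature block and the centered dummy-coded class
indicator is approximated by a rank-1 product ``a_h b_hᵀ`` under a lasso
penalty on ``a_h`` solved by soft-thresholding:

    a_h ← soft_threshold(M_h b_h, λ_h) / ‖·‖,   b_h ← M_hᵀ a_h / ‖·‖,

alternated to convergence. Sparsity is parameterized by a per-component
count ``keep[h]`` of retained features; λ_h is derived as the smallest
threshold that keeps exactly that many loadings nonzero. Both blocks are
regression-deflated by the latent variable ``t_h = X_h a_h`` before the
next component, which makes the latent variables mutually orthogonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import MetabolomicsDataset
from .decomposition import standardize

_MAX_ITER = 500
_TOL = 1e-9


class ConvergenceError(RuntimeError):
    def __init__(self, component: int, iterations: int, delta: float):
        self.component = component
        self.iterations = iterations
        self.delta = delta
        super().__init__(
            f"component {component}: no convergence after {iterations} "
            f"iterations (last delta {delta:.3e})"
        )


def soft_threshold(v: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise ``sign(v) · max(|v| − λ, 0)``."""
    if lam < 0:
        raise ValueError(f"threshold must be >= 0, got {lam}")
    v = np.asarray(v, dtype=float)
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def make_dummy(labels: np.ndarray) -> np.ndarray:
    """n × 2 class-indicator matrix (columns: control, tumor); rows sum to 1."""
    labels = np.asarray(labels, dtype=int)
    Y = np.zeros((labels.size, 2))
    Y[labels == 0, 0] = 1.0
    Y[labels == 1, 1] = 1.0
    return Y


def _threshold_top_k(u: np.ndarray, k: int) -> tuple[np.ndarray, float]:
    """Soft-threshold ``u`` at the smallest λ keeping exactly ``k`` nonzeros.

    Ties at the boundary are broken toward lower column index.
    """
    p = u.size
    if k >= p:
        return u.copy(), 0.0
    order = np.lexsort((np.arange(p), -np.abs(u)))  # |u| desc, index asc
    kept = order[:k]
    lam = float(np.abs(u[order[k]]))
    kth = float(np.abs(u[order[k - 1]]))
    if lam >= kth:  # tie across the boundary: shrink λ below the kept value
        below = np.abs(u)[np.abs(u) < kth]
        lam = float(below.max()) if below.size else 0.0
    a = np.zeros(p)
    a[kept] = np.sign(u[kept]) * (np.abs(u[kept]) - lam)
    return a, lam


@dataclass
class SplsdaModel:
    """Fitted sparse PLS-DA.

    ``loadings`` is p × H (columns ``a_h``, unit norm, ``keep[h]``
    nonzeros each), ``response_loadings`` q × H, ``latents`` n × H
    (``t_h = X_h a_h``), ``selected`` the per-component feature-name sets.
    """

    feature_names: list[str]
    H: int
    keep: tuple[int, ...]
    loadings: np.ndarray
    response_loadings: np.ndarray
    latents: np.ndarray
    lambdas: tuple[float, ...]
    selected: list[list[str]]

    def selected_union(self) -> list[str]:
        """All features selected on at least one component (dataset order)."""
        chosen = set().union(*map(set, self.selected)) if self.selected else set()
        return [n for n in self.feature_names if n in chosen]


def fit_splsda(
    ds: MetabolomicsDataset,
    H: int = 3,
    keep: tuple[int, ...] = (10, 10, 10),
) -> SplsdaModel:
    """Fit an ``H``-component sparse PLS-DA to a dataset.

    The feature block is standardized internally (missing entries imputed
    to the column mean); the response is the centered dummy matrix.
    """
    if H < 1:
        raise ValueError("H must be >= 1")
    if len(keep) != H:
        raise ValueError(f"keep must have one entry per component ({H})")
    p = ds.n_metabolites
    if any(not 1 <= k <= p for k in keep):
        raise ValueError(f"keep counts must be in 1..{p}")

    X = standardize(ds.values, ds.metabolite_names)
    Y = make_dummy(ds.labels)
    Y = Y - Y.mean(axis=0)

    n = X.shape[0]
    loadings = np.zeros((p, H))
    b_all = np.zeros((Y.shape[1], H))
    latents = np.zeros((n, H))
    lambdas = []
    selected: list[list[str]] = []

    for h in range(H):
        M = X.T @ Y
        # initialize b from the first right singular vector of M
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        b = vt[0]
        a = np.zeros(p)
        lam = 0.0
        for it in range(_MAX_ITER):
            u = M @ b
            a_new, lam = _threshold_top_k(u, keep[h])
            norm = np.linalg.norm(a_new)
            if norm == 0:
                raise ConvergenceError(h + 1, it + 1, float("nan"))
            a_new /= norm
            if np.dot(a_new, a) < 0:  # fix sign before measuring the change
                a_new = -a_new
            delta = np.linalg.norm(a_new - a)
            a = a_new
            c = M.T @ a
            b = c / np.linalg.norm(c)
            if delta < _TOL:
                break
        else:
            raise ConvergenceError(h + 1, _MAX_ITER, float(delta))

        t = X @ a
        tt = float(t @ t)
        loadings[:, h] = a
        b_all[:, h] = b
        latents[:, h] = t
        lambdas.append(lam)
        selected.append([ds.metabolite_names[j] for j in np.flatnonzero(a)])
        # regression deflation of both blocks
        X = X - np.outer(t, t @ X) / tt
        Y = Y - np.outer(t, t @ Y) / tt

    return SplsdaModel(
        feature_names=list(ds.metabolite_names),
        H=H,
        keep=tuple(keep),
        loadings=loadings,
        response_loadings=b_all,
        latents=latents,
        lambdas=tuple(lambdas),
        selected=selected,
    )


def selected_features(model: SplsdaModel):
    """Table of selected metabolites with component attribution.

    A metabolite nonzero on components 1 and 2 is attributed ``"1 and 2"``;
    metabolites selected nowhere are absent. Returns a pandas DataFrame
    with columns ``metabolite`` and ``components``, in dataset order.
    """
    import pandas as pd

    rows = []
    per_feature: dict[str, list[int]] = {}
    for h, names in enumerate(model.selected, start=1):
        for name in names:
            per_feature.setdefault(name, []).append(h)
    for name in model.feature_names:
        comps = per_feature.get(name)
        if comps:
            rows.append({"metabolite": name,
                         "components": " and ".join(map(str, comps))})
    return pd.DataFrame(rows, columns=["metabolite", "components"])


def lda_error(model: SplsdaModel, labels: np.ndarray) -> float:
    """Training misclassification rate of a two-class LDA on the latents.

    A sanity report only — feature selection, not classification, is the
    product of this module.
    """
    T = model.latents
    y = np.asarray(labels, dtype=int)
    mu0 = T[y == 0].mean(axis=0)
    mu1 = T[y == 1].mean(axis=0)
    centered = np.where(y[:, None] == 1, T - mu1, T - mu0)
    cov = centered.T @ centered / max(T.shape[0] - 2, 1)
    cov += 1e-10 * np.eye(cov.shape[0])
    w = np.linalg.solve(cov, mu1 - mu0)
    threshold = 0.5 * (w @ mu1 + w @ mu0)
    pred = (T @ w > threshold).astype(int)
    return float((pred != y).mean())
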