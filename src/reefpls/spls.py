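"""Sparse partial least squares (sPLS) regression core.

Predictors X are the physico-chemical variables, responses Y the microbial
features (taxa or GO terms).  Each component pairs an X-weight vector ``a``
and a Y-weight vector ``b`` maximizing cov(Xa, Yb) under cardinality
constraints: at every NIPALS half-step all but the ``k`` largest-magnitude
entries are zeroed and the survivors are shrunk by the (k+1)-th magnitude
(soft threshold).  Between components both blocks are deflated on the
X-scores (regression mode).

`SparsePLS` follows the scikit-learn estimator contract (get_params /
set_params / fit / fitted attributes with trailing underscores) and accepts
numpy arrays or DataFrames; feature names are kept when available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted


class SplsError(ValueError):
    pass


def soft_select(v: np.ndarray, k: int | None) -> np.ndarray:
    """Keep the k largest-magnitude entries, soft-thresholded by the (k+1)-th.

    Ties at the selection boundary are broken by index order (feature ids are
    carried in lexicographic order), so at most k entries survive.  In the
    degenerate all-tied case shrinking would zero everything; the kept
    entries are then left unshrunk.
    """
    v = np.asarray(v, dtype=float)
    p = v.size
    if k is None or k >= p:
        return v.copy()
    if k < 1:
        raise SplsError("keep must be >= 1")
    order = np.lexsort((np.arange(p), -np.abs(v)))  # |v| desc, then index asc
    thr = np.abs(v[order[k]])
    out = np.zeros_like(v)
    keep = order[:k]
    out[keep] = np.sign(v[keep]) * np.maximum(np.abs(v[keep]) - thr, 0.0)
    if not np.any(out):
        out[keep] = v[keep]
    return out


def _as_matrix(block, default_prefix: str):
    if isinstance(block, pd.DataFrame):
        return block.to_numpy(dtype=float), list(block.columns)
    arr = np.asarray(block, dtype=float)
    if arr.ndim != 2:
        raise SplsError("expected a 2-D block")
    return arr, [f"{default_prefix}{j}" for j in range(arr.shape[1])]


class SparsePLS(BaseEstimator):
    """Sparse PLS regression with per-component feature selection.

    Parameters
    ----------
    n_components : int
        Number of latent dimensions.
    keep_x, keep_y : int or None
        Nonzero weights retained per component in the predictor / response
        block; None keeps the full block (dense PLS).
    max_iter, tol : convergence of the alternating half-steps (max absolute
        change in the weight vectors).
    center, scale : bool
        Column centering / unit-variance scaling (sample SD) before fitting.

    Attributes (after fit)
    ----------------------
    x_weights_, y_weights_ : (p, H), (q, H) unit-norm weight vectors.
    x_scores_, y_scores_ : (n, H) latent scores (t, u).
    x_mean_, x_std_, y_mean_, y_std_ : scaling parameters.
    n_iter_ : iterations per component; converged_ : per-component flags.
    """

    def __init__(self, n_components: int = 2, keep_x: int | None = None,
                 keep_y: int | None = 50, max_iter: int = 100,
                 tol: float = 1e-6, center: bool = True, scale: bool = True):
        self.n_components = n_components
        self.keep_x = keep_x
        self.keep_y = keep_y
        self.max_iter = max_iter
        self.tol = tol
        self.center = center
        self.scale = scale

    # -- fitting ---------------------------------------------------------------
    def fit(self, X, Y):
        X, x_names = _as_matrix(X, "x")
        Y, y_names = _as_matrix(Y, "y")
        if X.shape[0] != Y.shape[0]:
            raise SplsError("X and Y must have the same number of rows")
        if self.tol <= 0:
            raise SplsError("tolerance must be positive")
        for keep, dim, name in ((self.keep_x, X.shape[1], "keep_x"),
                                (self.keep_y, Y.shape[1], "keep_y")):
            if keep is not None and not (1 <= keep):
                raise SplsError(f"{name} must be >= 1 or None")
        self.x_names_ = list(x_names)
        self.y_names_ = list(y_names)

        def _prep(A):
            mean = A.mean(axis=0) if self.center else np.zeros(A.shape[1])
            if self.scale:
                std = A.std(axis=0, ddof=1)
                std = np.where(std == 0, 1.0, std)
            else:
                std = np.ones(A.shape[1])
            return (A - mean) / std, mean, std

        Xc, self.x_mean_, self.x_std_ = _prep(X)
        Yc, self.y_mean_, self.y_std_ = _prep(Y)
        self._fit_core(Xc, Yc)
        return self

    def _fit_core(self, Xc: np.ndarray, Yc: np.ndarray):
        """NIPALS with soft selection on pre-normalized blocks."""
        n, p = Xc.shape
        q = Yc.shape[1]
        h_max = self.n_components
        A = np.zeros((p, h_max))
        B = np.zeros((q, h_max))
        T = np.zeros((n, h_max))
        U = np.zeros((n, h_max))
        self.n_iter_ = []
        self.converged_ = []
        Xd, Yd = Xc.copy(), Yc.copy()
        for h in range(h_max):
            M = Xd.T @ Yd
            # init b = dominant right singular vector of the cross-covariance
            _, _, vt = np.linalg.svd(M, full_matrices=False)
            b = vt[0]
            a = np.zeros(p)
            converged = False
            for it in range(1, self.max_iter + 1):
                a_new = soft_select(M @ b, self.keep_x)
                na = np.linalg.norm(a_new)
                if na == 0:
                    warnings.warn("X-weight collapsed to zero", stacklevel=2)
                    break
                a_new /= na
                b_new = soft_select(M.T @ a_new, self.keep_y)
                nb = np.linalg.norm(b_new)
                if nb == 0:
                    warnings.warn("Y-weight collapsed to zero", stacklevel=2)
                    break
                b_new /= nb
                delta = max(np.abs(a_new - a).max(), np.abs(b_new - b).max())
                a, b = a_new, b_new
                if delta < self.tol:
                    converged = True
                    break
            if not converged:
                warnings.warn(
                    f"component {h + 1} did not converge in {it} iterations",
                    stacklevel=2,
                )
            # deterministic sign: largest-|entry| of the X-weight is positive
            pivot = int(np.argmax(np.abs(a)))
            if a[pivot] < 0:
                a, b = -a, -b
            t = Xd @ a
            u = Yd @ b
            tt = t @ t
            if tt > 0:  # regression-mode deflation of both blocks on t
                Xd = Xd - np.outer(t, (t @ Xd) / tt)
                Yd = Yd - np.outer(t, (t @ Yd) / tt)
            A[:, h], B[:, h], T[:, h], U[:, h] = a, b, t, u
            self.n_iter_.append(it)
            self.converged_.append(converged)
        self.x_weights_ = A
        self.y_weights_ = B
        self.x_scores_ = T
        self.y_scores_ = U
        return self

    # -- inspection ------------------------------------------------------------
    def selected_features(self, component: int = 1) -> list[str]:
        """Response features with a nonzero weight on a component (1-based)."""
        check_is_fitted(self, "y_weights_")
        if not (1 <= component <= self.n_components):
            raise SplsError(f"component {component} out of range")
        mask = self.y_weights_[:, component - 1] != 0
        return [self.y_names_[j] for j in np.flatnonzero(mask)]

    def selected_predictors(self, component: int = 1) -> list[str]:
        check_is_fitted(self, "x_weights_")
        if not (1 <= component <= self.n_components):
            raise SplsError(f"component {component} out of range")
        mask = self.x_weights_[:, component - 1] != 0
        return [self.x_names_[j] for j in np.flatnonzero(mask)]


@dataclass
class SimilarityMatrix:
    """Env-variable x selected-feature association values with cluster order."""

    values: pd.DataFrame
    row_order: list = field(default_factory=list)
    col_order: list = field(default_factory=list)
    col_linkage: np.ndarray | None = None
    col_clusters: pd.Series | None = None


def _score_correlations(block: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """cor(column, score) per block column and component; zero-variance -> 0."""
    bc = block - block.mean(axis=0)
    sc = scores - scores.mean(axis=0)
    bnorm = np.linalg.norm(bc, axis=0)
    snorm = np.linalg.norm(sc, axis=0)
    bad = bnorm == 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} zero-variance columns; correlations set to 0",
                      stacklevel=2)
    bnorm = np.where(bad, 1.0, bnorm)
    snorm = np.where(snorm == 0, 1.0, snorm)
    cors = (bc.T @ sc) / np.outer(bnorm, snorm)
    cors[bad, :] = 0.0
    return cors


def similarity_matrix(model: SparsePLS, X, Y, components: int | None = None,
                      cluster: bool = True, n_clusters: int = 3) -> SimilarityMatrix:
    """Association heatmap values between predictors and selected responses.

    sim(i, j) = sum_h cor(X_i, t_h) * cor(Y_j, t_h) over the retained
    components (bounded by the component count via Cauchy-Schwarz), computed
    for responses selected on any retained component.  When ``cluster`` is
    set, rows and columns are ordered by complete-linkage clustering on
    Euclidean distance and columns carry a cluster label (cut at
    ``n_clusters``).
    """
    check_is_fitted(model, "x_weights_")
    H = components or model.n_components
    X, _ = _as_matrix(X, "x")
    Y, _ = _as_matrix(Y, "y")
    Xc = (X - model.x_mean_) / model.x_std_
    Yc = (Y - model.y_mean_) / model.y_std_
    T = model.x_scores_[:, :H]
    selected = sorted(
        {f for h in range(1, H + 1) for f in model.selected_features(h)},
        key=model.y_names_.index,
    )
    sel_idx = [model.y_names_.index(f) for f in selected]
    cx = _score_correlations(Xc, T)
    cy = _score_correlations(Yc[:, sel_idx], T)
    sim = cx @ cy.T
    values = pd.DataFrame(sim, index=pd.Index(model.x_names_, name="variable"),
                          columns=pd.Index(selected, name="feature"))
    result = SimilarityMatrix(values=values,
                              row_order=list(values.index),
                              col_order=list(values.columns))
    if cluster and values.shape[0] > 1 and values.shape[1] > 1:
        row_link = linkage(values.to_numpy(), method="complete", metric="euclidean")
        col_link = linkage(values.to_numpy().T, method="complete", metric="euclidean")
        result.row_order = [values.index[i] for i in leaves_list(row_link)]
        result.col_order = [values.columns[i] for i in leaves_list(col_link)]
        result.col_linkage = col_link
        k = min(n_clusters, values.shape[1])
        result.col_clusters = pd.Series(
            fcluster(col_link, t=k, criterion="maxclust"),
            index=values.columns, name="cluster",
        )
    return result


def spls_fit(X, Y, n_components: int = 2, keep_x: int | None = None,
             keep_y: int | None = 50, **kwargs) -> SparsePLS:
    """Functional wrapper over :class:`SparsePLS`."""
    return SparsePLS(n_components=n_components, keep_x=keep_x, keep_y=keep_y,
                     **kwargs).fit(X, Y)


def selected_features(model: SparsePLS, component: int = 1) -> list[str]:
    return model.selected_features(component)
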