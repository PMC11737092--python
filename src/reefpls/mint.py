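"""Multi-study (MINT) sparse PLS and leave-one-group-out stability scoring.

MINT integration centers and unit-variance scales every column *within each
study* (sampling trip) before a single sparse-PLS fit with one shared,
global set of loading vectors.  Per-study normalization removes additive
trip effects, so features are selected for covarying with the environment
consistently across trips rather than for tracking the trips themselves.

Leave-one-group-out cross-validation (LOGOCV) refits the model with each
study held out in turn; a feature's stability score is the fraction of the
``n_studies`` refits in which it was reselected on the chosen dimension,
giving the discrete score set {1/n, 2/n, ..., 1} (with four trips:
0.25 = trip-specific/unstable, >= 0.5 = shared across trips).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from sklearn.base import clone

from .spls import SparsePLS, SimilarityMatrix, _as_matrix


class MintError(ValueError):
    pass


def _check_studies(studies, n_rows: int) -> np.ndarray:
    s = np.asarray(pd.Series(studies).astype(str))
    if s.size != n_rows:
        raise MintError("studies must assign every sample")
    _, counts = np.unique(s, return_counts=True)
    if counts.min() < 3:
        raise MintError("every study needs at least 3 samples")
    return s


def within_study_scale(block, studies) -> np.ndarray:
    """Center and scale (sample SD) each column separately per study.

    A column constant within a study is set to 0 there, with a warning.
    """
    arr, _ = _as_matrix(block, "v")
    s = _check_studies(studies, arr.shape[0])
    out = np.empty_like(arr, dtype=float)
    warned = 0
    for study in np.unique(s):
        rows = s == study
        sub = arr[rows]
        mean = sub.mean(axis=0)
        std = sub.std(axis=0, ddof=1)
        zero = std == 0
        warned += int(zero.sum())
        std = np.where(zero, 1.0, std)
        scaled = (sub - mean) / std
        scaled[:, zero] = 0.0
        out[rows] = scaled
    if warned:
        warnings.warn(f"{warned} (study, column) blocks had zero variance; set to 0",
                      stacklevel=2)
    return out


class MintSparsePLS(SparsePLS):
    """Sparse PLS with per-study normalization and shared global loadings.

    Same parameters and fitted attributes as :class:`SparsePLS`; ``fit``
    additionally takes the study assignment.  With a single study this is
    identical to ``SparsePLS`` on globally scaled data.
    """

    def fit(self, X, Y, studies=None):
        if studies is None:
            raise MintError("MintSparsePLS.fit requires a study assignment")
        X_arr, x_names = _as_matrix(X, "x")
        Y_arr, y_names = _as_matrix(Y, "y")
        if X_arr.shape[0] != Y_arr.shape[0]:
            raise MintError("X and Y must have the same number of rows")
        self.x_names_ = list(x_names)
        self.y_names_ = list(y_names)
        self.studies_ = _check_studies(studies, X_arr.shape[0])
        Xs = within_study_scale(X_arr, self.studies_)
        Ys = within_study_scale(Y_arr, self.studies_)
        # scaling is per-study; record identity global parameters so that
        # similarity computations reuse the study-scaled geometry
        self.x_mean_ = np.zeros(X_arr.shape[1])
        self.x_std_ = np.ones(X_arr.shape[1])
        self.y_mean_ = np.zeros(Y_arr.shape[1])
        self.y_std_ = np.ones(Y_arr.shape[1])
        self._x_study_scaled_ = Xs
        self._y_study_scaled_ = Ys
        self._fit_core(Xs, Ys)
        return self


def mint_spls_fit(X, Y, studies, n_components: int = 2,
                  keep_x: int | None = None, keep_y: int | None = 50,
                  **kwargs) -> MintSparsePLS:
    """Functional wrapper over :class:`MintSparsePLS`."""
    return MintSparsePLS(n_components=n_components, keep_x=keep_x,
                         keep_y=keep_y, **kwargs).fit(X, Y, studies)


def logocv_stability(X, Y, studies, estimator: MintSparsePLS | None = None,
                     component: int = 1) -> pd.DataFrame:
    """Leave-one-study-out reselection stability per response feature.

    Refits the MINT model once per held-out study; the score is
    (#refits selecting the feature) / n_studies.  Returns one row per
    feature selected in at least one refit: columns are the score plus a
    boolean flag per held-out study.
    """
    estimator = estimator if estimator is not None else MintSparsePLS()
    X_arr, _ = _as_matrix(X, "x")
    Y_arr, y_names = _as_matrix(Y, "y")
    s = _check_studies(studies, X_arr.shape[0])
    study_ids = np.unique(s)
    if len(study_ids) < 2:
        raise MintError("LOGOCV needs at least 2 studies")
    flags = {}
    for held_out in study_ids:
        rows = s != held_out
        sub = clone(estimator)
        sub.fit(X_arr[rows], Y_arr[rows], studies=s[rows])
        # refits see positional column names; map back to the shared order
        pos = [sub.y_names_.index(f) for f in sub.selected_features(component)]
        flags[held_out] = {y_names[j] for j in pos}
    all_selected = sorted(set().union(*flags.values()), key=y_names.index)
    rows_out = []
    n = len(study_ids)
    for f in all_selected:
        sel = {f"left_out_{g}": f in flags[g] for g in study_ids}
        score = sum(sel.values()) / n
        rows_out.append({"feature": f, "score": score, **sel})
    out = pd.DataFrame(rows_out,
                       columns=["feature", "score",
                                *[f"left_out_{g}" for g in study_ids]])
    return out.set_index("feature")


@dataclass
class ScenarioCounts:
    """Combinatorics of nonempty LOGOCV selection patterns."""

    n_studies: int
    total: int
    by_score: dict


def enumerate_logocv_scenarios(n_studies: int) -> ScenarioCounts:
    """Count the 2^n - 1 nonempty selection patterns, grouped by score k/n."""
    if n_studies < 1:
        raise MintError("n_studies must be >= 1")
    by_score = {k / n_studies: comb(n_studies, k)
                for k in range(1, n_studies + 1)}
    return ScenarioCounts(n_studies=n_studies,
                          total=2 ** n_studies - 1,
                          by_score=by_score)


def stable_indicator_report(scores: pd.DataFrame, similarity: SimilarityMatrix,
                            stable_threshold: float = 0.5) -> pd.DataFrame:
    """Join LOGOCV scores to heatmap cluster membership.

    One row per feature in the similarity matrix (features selected on the
    retained components of the full fit); features without a LOGOCV
    selection score 0.  Flags the cluster most enriched in stable
    (score >= threshold) features.
    """
    features = list(similarity.values.columns)
    clusters = similarity.col_clusters
    rows = []
    for f in features:
        score = float(scores["score"].get(f, 0.0)) if len(scores) else 0.0
        rows.append({
            "feature": f,
            "score": score,
            "stable": score >= stable_threshold,
            "cluster": int(clusters.loc[f]) if clusters is not None else 1,
        })
    out = pd.DataFrame(rows).set_index("feature")
    enrich = out.groupby("cluster")["stable"].mean()
    out.attrs["enriched_cluster"] = (int(enrich.idxmax())
                                     if enrich.max() > 0 else None)
    out.attrs["n_stable"] = int(out["stable"].sum())
    return out
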