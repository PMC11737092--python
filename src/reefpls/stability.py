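"""Repeated k-fold reselection stability of per-trip sPLS indicators.

For each (trip, dataset) model the full-data sparse PLS fit defines the
component-1 indicator set; repeated random fourfold partitions then refit
the model on each fold's complement, and an indicator's stability is the
fraction of the n_folds x n_repeats runs in which it was reselected.  The
taxa-vs-GO contrast compares the two stability vectors of a trip with a
two-sided Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone

from .containers import CountTable, EnvTable
from .community import wilcoxon_rank_sum
from .preprocess import clr_transform
from .spls import SparsePLS, _as_matrix


class StabilityError(ValueError):
    pass


@dataclass
class CvStabilityResult:
    """Reselection frequencies from repeated k-fold refits."""

    stability: pd.Series           # full-fit indicators only
    full_table: pd.Series          # every response feature
    indicator_set: list
    n_folds: int
    n_repeats: int
    seed: int | None
    trip: str | None = None
    dataset: str | None = None

    @property
    def n_runs(self) -> int:
        return self.n_folds * self.n_repeats


def _fold_partition(n: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random near-equal partition of range(n) into n_folds folds."""
    perm = rng.permutation(n)
    return np.array_split(perm, n_folds)


def cv_stability(X, Y, estimator: SparsePLS | None = None, n_folds: int = 4,
                 n_repeats: int = 50, seed: int | None = None,
                 component: int = 1, trip: str | None = None,
                 dataset: str | None = None) -> CvStabilityResult:
    """Repeated k-fold reselection stability on one model's samples.

    Every fold's complement refits the estimator with unchanged settings;
    non-convergent refits still contribute their returned selection.
    """
    estimator = estimator if estimator is not None else SparsePLS()
    X_arr, _ = _as_matrix(X, "x")
    Y_arr, y_names = _as_matrix(Y, "y")
    n = X_arr.shape[0]
    if n < n_folds:
        raise StabilityError("fewer samples than folds")
    if n // n_folds < 2:
        raise StabilityError("folds would leave <2 samples for refitting")
    keep = estimator.get_params().get("keep_y")
    if keep is not None and keep > Y_arr.shape[1]:
        raise StabilityError("keep_y larger than the number of features")

    full = clone(estimator).fit(X_arr, Y_arr)
    pos_of = {name: j for j, name in enumerate(full.y_names_)}
    indicator_idx = [pos_of[f] for f in full.selected_features(component)]

    counts = np.zeros(Y_arr.shape[1])
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.spawn(n_repeats)
    for r in range(n_repeats):
        rng = np.random.default_rng(repeat_seeds[r])
        for fold in _fold_partition(n, n_folds, rng):
            train = np.setdiff1d(np.arange(n), fold)
            sub = clone(estimator).fit(X_arr[train], Y_arr[train])
            for f in sub.selected_features(component):
                counts[pos_of[f]] += 1
    total = n_folds * n_repeats
    full_table = pd.Series(counts / total, index=y_names, name="stability")
    indicators = [y_names[j] for j in indicator_idx]
    return CvStabilityResult(
        stability=full_table.loc[indicators],
        full_table=full_table,
        indicator_set=indicators,
        n_folds=n_folds, n_repeats=n_repeats, seed=seed,
        trip=trip, dataset=dataset,
    )


@dataclass
class ModelSpec:
    """One (trip, dataset) sparse-PLS model restricted to that trip's samples."""

    trip: str
    dataset: str
    sample_ids: list
    site_ids: list


def build_model_grid(taxa: CountTable, go: CountTable, env: EnvTable) -> list[ModelSpec]:
    """The per-trip model grid: one spec per (trip, dataset) combination."""
    specs = []
    trips = sorted(taxa.samples["trip"].unique())
    go_trips = sorted(go.samples["trip"].unique())
    if trips != go_trips:
        raise StabilityError("taxa and GO tables disagree on trips")
    for trip in trips:
        for dataset, table in (("taxonomy", taxa), ("go", go)):
            mask = table.samples["trip"] == trip
            ids = list(table.samples.index[mask])
            sites = sorted(table.samples.loc[ids, "site"].unique())
            specs.append(ModelSpec(trip=trip, dataset=dataset,
                                   sample_ids=ids, site_ids=sites))
    return specs


def model_inputs(spec: ModelSpec, table: CountTable, env: EnvTable,
                 pseudocount: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(X, Y) for a model spec: per-sample env rows and CLR feature values."""
    sub = table.restrict_samples(spec.sample_ids)
    X = env.for_samples(sub.samples)
    Y = clr_transform(sub, pseudocount=pseudocount).values
    return X, Y


@dataclass
class StabilityComparison:
    trip: str
    median_taxa: float
    sd_taxa: float
    median_go: float
    sd_go: float
    statistic: float
    p: float
    stars: str


def _stars(p: float) -> str:
    for thr, s in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if p < thr:
            return s
    return "ns"


def compare_stability(taxa_result: CvStabilityResult,
                      go_result: CvStabilityResult) -> StabilityComparison:
    """Taxa-vs-GO Wilcoxon contrast of one trip's indicator stability vectors."""
    if taxa_result.trip != go_result.trip:
        raise StabilityError(
            f"results from different trips: {taxa_result.trip!r} vs {go_result.trip!r}"
        )
    tv = taxa_result.stability.to_numpy()
    gv = go_result.stability.to_numpy()
    stat, p = wilcoxon_rank_sum(tv, gv)
    return StabilityComparison(
        trip=taxa_result.trip or "",
        median_taxa=float(np.median(tv)), sd_taxa=float(np.std(tv, ddof=1)),
        median_go=float(np.median(gv)), sd_go=float(np.std(gv, ddof=1)),
        statistic=stat, p=p, stars=_stars(p),
    )
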