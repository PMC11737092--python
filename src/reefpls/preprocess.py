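"""Post-annotation filtering, compositional transforms, and env aggregation.

The filtering chain mirrors read-based metagenome practice: drop unannotated,
eukaryote, virus and domain-level-only features first, then remove rare
features whose share of the remaining grand total falls strictly below a
relative-abundance threshold (default 0.0001% = 1e-6).  Abundances are made
comparable either as per-sample proportions or through the centered log-ratio
(CLR) transform with a pseudocount, the natural geometry for compositional
count data.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import ClrMatrix, CountTable, EnvTable, EXCLUDED_CLASSES


class PreprocessError(ValueError):
    pass


def filter_features(
    t: CountTable,
    min_rel_abundance: float = 1e-6,
    per_sample: bool = False,
) -> tuple[CountTable, pd.DataFrame]:
    """Apply annotation-class and rare-feature filters.

    Class filters remove features classed unannotated, eukaryote, virus or
    domain_only.  The abundance filter then drops features whose relative
    abundance is strictly below ``min_rel_abundance``; by default the
    abundance is the feature's share of the grand total of the remaining
    counts (``per_sample=True`` instead keeps a feature if its per-sample
    relative abundance reaches the threshold in at least one sample).

    Returns the filtered table and a removal report (rule, feature_id, value).
    """
    report_rows = []
    rule_names = {
        "unannotated": "1:non-annotated",
        "eukaryote": "2:eukaryote",
        "virus": "3:virus",
        "domain_only": "4:domain-level-only",
    }
    classes = t.features["annotation"]
    keep_mask = ~classes.isin(EXCLUDED_CLASSES)
    for fid in t.feature_ids[~keep_mask]:
        report_rows.append({
            "rule": rule_names[classes.loc[fid]],
            "feature_id": fid,
            "value": float(t.counts[fid].sum()),
        })
    if not keep_mask.any():
        last = classes[~keep_mask].iloc[-1]
        raise PreprocessError(
            f"no features left after class filter (last removal rule: "
            f"{rule_names[last]})"
        )
    kept = t.restrict_features(t.feature_ids[keep_mask])

    counts = kept.counts
    if per_sample:
        row_sums = counts.sum(axis=1).replace(0, np.nan)
        rel = counts.div(row_sums, axis=0)
        abundant = (rel >= min_rel_abundance).any(axis=0)
        values = rel.max(axis=0)
    else:
        grand = counts.to_numpy().sum()
        values = counts.sum(axis=0) / grand
        abundant = values >= min_rel_abundance
    for fid in counts.columns[~abundant]:
        report_rows.append({
            "rule": "5:rare", "feature_id": fid, "value": float(values.loc[fid]),
        })
    if not abundant.any():
        raise PreprocessError(
            "no features left after rare-feature filter (rule 5:rare)"
        )
    out = kept.restrict_features(counts.columns[abundant])
    report = pd.DataFrame(report_rows, columns=["rule", "feature_id", "value"])
    return out, report


def relative_abundance(t) -> pd.DataFrame:
    """Per-sample proportions (each row divided by its sum)."""
    counts = t.counts if isinstance(t, CountTable) else pd.DataFrame(t)
    sums = counts.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise PreprocessError(f"zero-sum sample(s): {list(zero.index)[:5]}")
    return counts.div(sums, axis=0)


def clr_transform(t, pseudocount: float = 1.0) -> ClrMatrix:
    """Centered log-ratio transform after adding a pseudocount.

    Per sample, ``v_i = ln(x_i + c) - mean_j ln(x_j + c)``; output rows sum
    to zero.
    """
    if pseudocount <= 0:
        raise PreprocessError("pseudocount must be positive")
    counts = t.counts if isinstance(t, CountTable) else pd.DataFrame(t)
    logs = np.log(counts.to_numpy(dtype=float) + pseudocount)
    vals = logs - logs.mean(axis=1, keepdims=True)
    return ClrMatrix(
        values=pd.DataFrame(vals, index=counts.index, columns=counts.columns),
        pseudocount=pseudocount,
        source=type(t).__name__,
    )


def collapse(t: CountTable, level: str) -> CountTable:
    """Sum counts over features sharing a hierarchical rank label.

    Features whose path does not resolve at ``level`` are grouped under the
    sentinel label ``unresolved_<level>`` and a warning is emitted.
    """
    ranks = t.rank_names
    if level not in ranks:
        raise PreprocessError(f"unknown rank {level!r}; table has {ranks}")
    sentinel = f"unresolved_{level}"
    labels = t.features[level]
    unresolved = labels.isna() | (labels == "")
    if unresolved.any():
        warnings.warn(
            f"{int(unresolved.sum())} features unresolved at {level!r}; "
            f"grouped under {sentinel!r}", stacklevel=2,
        )
    labels = labels.where(~unresolved, sentinel)
    grouped = t.counts.T.groupby(labels.values, sort=True).sum().T
    grouped.columns.name = "feature_id"

    keep_ranks = ranks[: ranks.index(level) + 1]
    feat_meta = t.features.assign(_label=labels.values)
    new_features = (
        feat_meta.groupby("_label", sort=True)
        .agg({**{r: "first" for r in keep_ranks}, "annotation": "first"})
    )
    new_features.loc[new_features.index == sentinel, keep_ranks] = sentinel
    new_features.index.name = "feature_id"
    new_features = new_features[["annotation"] + keep_ranks]
    return CountTable(counts=grouped, samples=t.samples.copy(),
                      features=new_features.loc[grouped.columns])


def aggregate_env_medians(replicates: pd.DataFrame) -> EnvTable:
    """Per-site medians of replicate water-chemistry measurements.

    ``replicates`` holds one row per deployment with ``trip`` and ``site``
    columns plus one column per variable; missing replicate values (NaN) are
    ignored, and a cell with no non-missing replicate stays missing.
    """
    for col in ("trip", "site"):
        if col not in replicates.columns:
            raise PreprocessError(f"replicate table needs a {col!r} column")
    variables = [c for c in replicates.columns if c not in ("trip", "site")]
    med = replicates.groupby("site", sort=True)[variables].median()
    trips = replicates.groupby("site", sort=True)["trip"].first()
    return EnvTable(values=med, trips=trips)


def scale_env_for_heatmap(e: EnvTable) -> pd.DataFrame:
    """Center each variable to median 0 and scale to sample SD 1 across sites."""
    vals = e.values
    out = {}
    for var in vals.columns:
        col = vals[var]
        if col.notna().sum() < 2:
            raise PreprocessError(f"variable {var!r} has <2 non-missing sites")
        sd = col.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise PreprocessError(f"variable {var!r} has zero SD across sites")
        out[var] = (col - col.median()) / sd
    return pd.DataFrame(out, index=vals.index)


def impute_env_by_trip_median(e: EnvTable) -> EnvTable:
    """Fill missing cells with the within-trip median of that variable.

    Used before sparse PLS, which needs a complete predictor matrix; cells
    missing for a whole trip fall back to the overall median.
    """
    vals = e.values.copy()
    trip_of = e.trips
    for var in vals.columns:
        col = vals[var]
        if not col.isna().any():
            continue
        trip_med = col.groupby(trip_of).transform("median")
        col = col.fillna(trip_med).fillna(col.median())
        vals[var] = col
    return EnvTable(values=vals, trips=e.trips.copy())


class CLRTransformer(TransformerMixin, BaseEstimator):
    """scikit-learn transformer wrapping :func:`clr_transform`."""

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.pseudocount <= 0:
            raise PreprocessError("pseudocount must be positive")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        logs = np.log(X + self.pseudocount)
        return logs - logs.mean(axis=1, keepdims=True)
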