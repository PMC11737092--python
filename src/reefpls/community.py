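"""Community summaries: diversity, within-site similarity, PCA, group tests.

Shannon diversity is reported in nats (natural log), matching the log base
used by the CLR transform.  PERMANOVA is computed directly from a distance
matrix (pseudo-F with label permutations) so that per-pair R^2 and explicit
seeding are available; pairwise tests are Bonferroni-adjusted by default.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis as _braycurtis, pdist, squareform
from scipy.stats import mannwhitneyu
from sklearn.decomposition import PCA as _PCA
from statsmodels.stats.multitest import multipletests

from .containers import ClrMatrix, CountTable, DistanceMatrix
from .preprocess import collapse, relative_abundance


class CommunityStatsError(ValueError):
    pass


def shannon(x) -> float:
    """Shannon index H = -sum p_i ln p_i (nats) of a count/proportion vector."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise CommunityStatsError("shannon expects a 1-D vector")
    if (x < 0).any():
        raise CommunityStatsError("negative entries")
    total = x.sum()
    if total == 0:
        raise CommunityStatsError("all-zero vector has no diversity")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum a + sum b), in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise CommunityStatsError("vectors must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise CommunityStatsError("negative entries")
    if a.sum() == 0 and b.sum() == 0:
        raise CommunityStatsError("both vectors are all-zero")
    return float(_braycurtis(a, b))


def bray_curtis_matrix(table: pd.DataFrame) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances between the rows of ``table``."""
    d = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        values=pd.DataFrame(d, index=table.index, columns=table.index),
        metric="braycurtis",
    )


def euclidean_matrix(table: pd.DataFrame, standardize: bool = False) -> DistanceMatrix:
    """Euclidean distances between rows, optionally after z-scoring columns.

    Missing cells are excluded pairwise (scaled masked Euclidean distance).
    """
    x = table.to_numpy(dtype=float)
    if standardize:
        mu = np.nanmean(x, axis=0)
        sd = np.nanstd(x, axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - mu) / sd
    if np.isnan(x).any():
        n = x.shape[0]
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~np.isnan(x[i]) & ~np.isnan(x[j])
                if not ok.any():
                    raise CommunityStatsError(
                        f"rows {table.index[i]!r}/{table.index[j]!r} share no variables"
                    )
                diff = x[i, ok] - x[j, ok]
                d[i, j] = d[j, i] = np.sqrt((diff ** 2).sum() * x.shape[1] / ok.sum())
    else:
        d = squareform(pdist(x, metric="euclidean"))
    return DistanceMatrix(
        values=pd.DataFrame(d, index=table.index, columns=table.index),
        metric="euclidean",
    )


def within_site_similarity(t: CountTable, level: str) -> tuple[pd.DataFrame, dict]:
    """Pairwise within-site Bray-Curtis similarities at a hierarchical level.

    For each site with >= 2 replicates, all C(r, 2) pairwise similarities
    (1 - Bray-Curtis on relative abundances of the level-collapsed table) are
    computed.  Returns a long table (site, sample_a, sample_b, similarity)
    and a summary dict (level, n_values, median, sd, min).
    """
    collapsed = collapse(t, level)
    rel = relative_abundance(collapsed)
    rows = []
    for site, members in collapsed.samples.groupby("site").groups.items():
        if len(members) < 2:
            warnings.warn(f"site {site!r} has <2 replicates; skipped", stacklevel=2)
            continue
        for a, b in itertools.combinations(list(members), 2):
            sim = 1.0 - bray_curtis(rel.loc[a], rel.loc[b])
            rows.append({"site": site, "sample_a": a, "sample_b": b,
                         "similarity": sim})
    values = pd.DataFrame(rows, columns=["site", "sample_a", "sample_b", "similarity"])
    sims = values["similarity"].to_numpy()
    summary = {
        "level": level,
        "n_values": int(len(sims)),
        "median": float(np.median(sims)) if len(sims) else np.nan,
        "sd": float(np.std(sims, ddof=1)) if len(sims) > 1 else np.nan,
        "min": float(sims.min()) if len(sims) else np.nan,
    }
    return values, summary


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca(m, n_components: int | None = None) -> PcaResult:
    """Column-centered PCA (SVD) of a CLR matrix or plain DataFrame."""
    table = m.values if isinstance(m, ClrMatrix) else pd.DataFrame(m)
    x = table.to_numpy(dtype=float)
    if x.shape[0] < 2:
        raise CommunityStatsError("PCA needs at least 2 samples")
    if np.allclose(x.var(axis=0), 0):
        raise CommunityStatsError("zero-variance input")
    k = n_components or min(x.shape[0] - 1, x.shape[1])
    k = min(k, x.shape[0] - 1, x.shape[1])
    model = _PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(x)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=table.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=table.columns,
                              columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
    )


def _permanova_stats(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """One-way PERMANOVA pseudo-F and R^2 from squared distances."""
    n = d2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    a = len(groups)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    for g, ng in zip(groups, counts):
        idx = np.flatnonzero(labels == g)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(ng, 1)].sum() / ng
    ssa = sst - ssw
    f = (ssa / (a - 1)) / (ssw / (n - a))
    r2 = ssa / sst
    return f, r2


def permanova(
    d: DistanceMatrix, groups, n_perm: int = 999, seed: int | None = None
) -> dict:
    """PERMANOVA on a distance matrix with label permutations.

    p = (1 + #{permuted F >= observed}) / (1 + n_perm).
    """
    labels = np.asarray(pd.Series(groups, index=d.ids).loc[d.ids])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise CommunityStatsError("need at least two groups")
    if counts.min() < 2:
        raise CommunityStatsError("every group needs at least 2 members")
    d2 = d.values.to_numpy() ** 2
    f_obs, r2 = _permanova_stats(d2, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _permanova_stats(d2, rng.permutation(labels))
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return {"F": f_obs, "R2": r2, "p": p, "n_permutations": n_perm}


def permanova_pairwise(
    d: DistanceMatrix,
    groups,
    n_perm: int = 999,
    correction: str = "bonferroni",
    seed: int | None = None,
) -> pd.DataFrame:
    """One-way PERMANOVA for every pair of groups, with p adjustment."""
    labels = pd.Series(groups, index=d.ids).loc[d.ids]
    names = sorted(labels.unique())
    pairs = list(itertools.combinations(names, 2))
    rng = np.random.default_rng(seed)
    rows = []
    for g1, g2 in pairs:
        ids = labels.index[labels.isin([g1, g2])]
        sub = DistanceMatrix(values=d.values.loc[ids, ids], metric=d.metric)
        res = permanova(sub, labels.loc[ids], n_perm=n_perm,
                        seed=int(rng.integers(2 ** 31)))
        rows.append({"group_1": g1, "group_2": g2, "F": res["F"],
                     "R2": res["R2"], "p": res["p"]})
    out = pd.DataFrame(rows)
    if correction == "bonferroni":
        out["p_adj"] = np.minimum(out["p"] * len(pairs), 1.0)
    elif correction == "holm":
        out["p_adj"] = multipletests(out["p"], method="holm")[1]
    else:
        raise CommunityStatsError(f"unknown correction {correction!r}")
    return out


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when both samples have n <= 8 and there are no ties;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise CommunityStatsError("empty sample")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (x.size <= 8 and y.size <= 8 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pairwise_wilcoxon(groups: dict, adjust: str = "holm") -> pd.DataFrame:
    """Rank-sum test for every pair of named groups with p adjustment."""
    names = sorted(groups)
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        stat, p = wilcoxon_rank_sum(groups[g1], groups[g2])
        rows.append({"group_1": g1, "group_2": g2, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        method = {"holm": "holm", "bonferroni": "bonferroni"}[adjust]
        out["p_adj"] = multipletests(out["p"], method=method)[1]
    return out
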