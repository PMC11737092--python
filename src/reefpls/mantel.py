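"""Geographic-distance-corrected (partial) Mantel screen.

Associates community distances (Bray-Curtis on relative abundances) with the
Euclidean distance of each physico-chemical variable while controlling for
great-circle distance between reef sites.  The partial statistic is the rank
(Spearman) correlation between the residuals of the community and environment
distance vectors after regressing each on the geographic distance vector;
inference comes from simultaneous row/column permutation of the community
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import DistanceMatrix, EnvTable
from .community import bray_curtis_matrix, euclidean_matrix
from .preprocess import relative_abundance

EARTH_RADIUS_KM = 6371.0


class MantelError(ValueError):
    pass


@dataclass
class MantelResult:
    variable: str
    rho: float
    p: float
    n_permutations: int
    p_adjusted: float
    dataset: str


def geo_distance_km(latlon: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between sites.

    ``latlon`` has one row per site with ``lat``/``lon`` columns in degrees.
    """
    lat = np.asarray(latlon["lat"], dtype=float)
    lon = np.asarray(latlon["lon"], dtype=float)
    if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
        raise MantelError("coordinates out of range (|lat|<=90, |lon|<=180)")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    h = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(
        values=pd.DataFrame(d, index=latlon.index, columns=latlon.index),
        metric="geographic-km",
    )


def _residualize(v: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Residuals of v on [1, covariate] (least squares, rank-deficiency safe)."""
    design = np.column_stack([np.ones_like(covariate), covariate])
    coef, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ coef


def _prepare(vec: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        return rankdata(vec)
    if method == "pearson":
        return vec.astype(float)
    raise MantelError(f"unknown method {method!r}")


def partial_mantel(
    d_comm: DistanceMatrix,
    d_env: DistanceMatrix,
    d_geo: DistanceMatrix,
    method: str = "spearman",
    n_perm: int = 10_000,
    seed: int | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Partial Mantel test of d_comm vs d_env controlling for d_geo.

    One-sided (positive association) by default; ``alternative='two-sided'``
    doubles the smaller tail.  p = (1 + #{perm stat >= observed}) / (1 + n_perm).
    """
    ids = d_comm.ids
    for other in (d_env, d_geo):
        if list(other.ids) != list(ids):
            raise MantelError("distance matrices must share the same items")
    n = len(ids)
    if n < 4:
        raise MantelError("need at least 4 items")
    iu = np.triu_indices(n, k=1)
    comm_m = d_comm.values.to_numpy()
    env_v = _prepare(d_env.values.to_numpy()[iu], method)
    geo_v = _prepare(d_geo.values.to_numpy()[iu], method)
    comm_v = _prepare(comm_m[iu], method)
    if np.std(comm_v) == 0 or np.std(env_v) == 0:
        raise MantelError("constant distance matrix (zero variance)")

    # orthonormal basis of [1, geo]; shared by every permutation
    design = np.column_stack([np.ones_like(geo_v), geo_v])
    q, _ = np.linalg.qr(design)
    q = q[:, : np.linalg.matrix_rank(design)]

    def _residual(v: np.ndarray) -> np.ndarray:
        r = v - q @ (q.T @ v)
        return r - r.mean()

    env_res = _residual(env_v)
    env_norm = np.linalg.norm(env_res)

    def stat(comm_vec: np.ndarray) -> float:
        r = _residual(_prepare(comm_vec, method))
        denom = np.linalg.norm(r) * env_norm
        if denom == 0:
            return 0.0
        return float(r @ env_res / denom)

    obs = stat(comm_m[iu])
    rng = np.random.default_rng(seed)
    ge = 0
    le = 0
    # permutations processed in vectorized blocks (rank + residual per row)
    for start in range(0, n_perm, 256):
        block = min(256, n_perm - start)
        perms = np.array([rng.permutation(n) for _ in range(block)])
        pm = comm_m[perms[:, :, None], perms[:, None, :]][:, iu[0], iu[1]]
        if method == "spearman":
            pm = rankdata(pm, axis=1)
        r = pm - (pm @ q) @ q.T
        r -= r.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(r, axis=1) * env_norm
        denom[denom == 0] = np.inf
        stats = (r @ env_res) / denom
        ge += int((stats >= obs).sum())
        le += int((stats <= obs).sum())
    if alternative == "greater":
        p = (1 + ge) / (1 + n_perm)
    elif alternative == "two-sided":
        p = min(1.0, 2 * min((1 + ge) / (1 + n_perm), (1 + le) / (1 + n_perm)))
    else:
        raise MantelError(f"unknown alternative {alternative!r}")
    return MantelResult(variable="", rho=obs, p=p, n_permutations=n_perm,
                        p_adjusted=p, dataset="")


def site_level_proportions(count_table) -> pd.DataFrame:
    """Mean relative abundance per site (replicates averaged)."""
    rel = relative_abundance(count_table)
    site = count_table.samples["site"]
    return rel.groupby(site.values).mean()


def mantel_screen(
    community_tables: dict,
    env: EnvTable,
    latlon: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    family: str = "per-dataset",
    standardize_env: bool = True,
) -> pd.DataFrame:
    """Partial Mantel test per (dataset, environment variable).

    ``community_tables`` maps dataset labels (e.g. 'taxonomy', 'go') to
    CountTables; per-site mean proportions feed Bray-Curtis distances.  Each
    variable's distance is |difference| of (optionally z-scored) site values,
    missing cells excluded pairwise.  Bonferroni adjustment uses the
    per-dataset family (17 tests) by default; ``family='global'`` adjusts
    over all tests of the screen.
    """
    geo = geo_distance_km(latlon.loc[env.sites])
    rng = np.random.default_rng(seed)
    rows = []
    for label, table in community_tables.items():
        props = site_level_proportions(table).loc[env.sites]
        d_comm = bray_curtis_matrix(props)
        for var in env.variables:
            col = env.values[[var]]
            if col[var].isna().all():
                raise MantelError(f"variable {var!r} entirely missing")
            d_env = euclidean_matrix(col, standardize=standardize_env)
            res = partial_mantel(d_comm, d_env, geo, n_perm=n_perm,
                                 seed=int(rng.integers(2 ** 31)))
            rows.append({"dataset": label, "variable": var, "rho": res.rho,
                         "p": res.p, "n_permutations": n_perm})
    out = pd.DataFrame(rows)
    if family == "per-dataset":
        k = out.groupby("dataset")["p"].transform("size")
    elif family == "global":
        k = len(out)
    else:
        raise MantelError(f"unknown family {family!r}")
    out["p_adj"] = np.minimum(out["p"] * k, 1.0)
    out["significant"] = out["p_adj"] < alpha
    return out
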