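"""Synthetic reef-seawater metagenome generator with known ground truth.

Emulates the structure of a multi-trip offshore reef survey: four sampling
trips, ~12 reef sites per trip, four replicate seawater samples per site,
genus-level taxon counts, GO-term counts obtained by summing member taxa, and
a site-level table of 17 physico-chemical variables organised in two
collinear blocks (particulate nutrients + chlorophyll vs dissolved
nutrients).

The generative model is hierarchical log-normal + multinomial:

* every GO group (and every unmapped taxon) has a latent log-abundance =
  baseline ``N(0, base_abundance_sd^2)`` + per-trip batch shift
  ``N(0, batch_sd^2)`` + replicate noise; planted indicator GO groups
  additionally gain ``effect_size * z`` where ``z`` is the standardized
  site value of their designated environment variable — so the planted
  slope is exact at the GO level;
* within a GO group the probability mass is split among the ``redundancy``
  member taxa by a softmax over member preferences with a *dominant
  carrier*: each trip has a preferred carrier (rotated across trips), each
  site adopts it with probability ``carrier_fidelity`` or picks another
  member, and per-sample membership noise is added on top.  Member taxa
  therefore inherit the full environmental slope but with large site-level
  membership noise — functional redundancy makes the GO signal cleaner
  than any single taxon's;
* counts are one multinomial draw per sample over the softmax of taxon-level
  latents (group latent + log membership weight) at a Poisson library size;
  GO counts are exact member sums by construction.

Everything is driven by a single seeded ``numpy`` Generator, so a config
reproduces its dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CountTable, EnvTable

ENV_VARIABLES = [
    "Chl-a", "Phaeo", "PN", "POC", "PP", "DOC", "PO4", "NH4", "NO2", "NO3",
    "Si", "TDN", "TDP", "TSS", "Temperature", "Salinity", "Chl-a fluorescence",
]
#: particulate nutrients + chlorophyll pigments (block 1)
PARTICULATE_BLOCK = ["Chl-a", "Phaeo", "PN", "POC", "PP", "TSS", "Chl-a fluorescence"]
#: dissolved nutrients + DOC (block 2)
DISSOLVED_BLOCK = ["DOC", "PO4", "NH4", "NO2", "NO3", "Si", "TDN", "TDP"]

# plausible measurement scales (location, spread) per variable; locations sit
# well above zero so concentrations stay non-negative
_ENV_SCALES = {
    "Chl-a": (0.45, 0.08), "Phaeo": (0.40, 0.07), "PN": (1.2, 0.2),
    "POC": (8.0, 1.2), "PP": (0.06, 0.01), "DOC": (75.0, 8.0),
    "PO4": (0.07, 0.012), "NH4": (0.12, 0.02), "NO2": (0.05, 0.008),
    "NO3": (0.20, 0.03), "Si": (1.5, 0.25), "TDN": (5.0, 0.7),
    "TDP": (0.25, 0.04), "TSS": (1.8, 0.3), "Temperature": (27.0, 1.6),
    "Salinity": (35.2, 0.35), "Chl-a fluorescence": (0.30, 0.05),
}

TAXONOMY_RANKS = ["domain", "phylum", "class", "order", "family", "genus"]
GO_RANKS = ["rank3", "rank4", "rank5"]


class SimConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-design and effect-size parameters of the generator.

    ``effect_size`` is the planted slope in CLR units per standard deviation
    of the designated environment variable; ``batch_sd`` the SD of the
    per-trip additive shift of GO-group log-abundances; ``carrier_boost``
    the log-preference of a site's dominant member taxon within its GO
    group, and ``carrier_fidelity`` the probability that a site's dominant
    member is the trip's preferred (trip-rotated) carrier.
    """

    n_trips: int = 4
    sites_per_trip: int = 12
    replicates_per_site: int = 4
    n_taxa: int = 600
    n_go: int = 150
    redundancy: int = 4
    n_env: int = 17
    n_indicator_go: int = 40
    effect_size: float = 1.0
    batch_sd: float = 0.5
    library_size_mean: float = 50_000.0
    seed: int = 0
    # secondary noise/structure knobs
    base_abundance_sd: float = 1.5
    feature_noise_sd: float = 0.6
    member_base_sd: float = 1.0
    member_noise_sd: float = 0.75
    carrier_boost: float = 2.0
    carrier_fidelity: float = 0.5
    env_block_cor: float = 0.7
    env_trip_sd: float = 1.0
    indicator_env_vars: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        for name in ("n_trips", "sites_per_trip", "replicates_per_site",
                     "n_taxa", "n_go", "n_env"):
            if getattr(self, name) < 1:
                raise SimConfigError(f"{name} must be >= 1")
        if self.redundancy < 1:
            raise SimConfigError("redundancy must be >= 1")
        if self.n_indicator_go > self.n_go:
            raise SimConfigError("n_indicator_go cannot exceed n_go")
        if self.effect_size < 0:
            raise SimConfigError("effect_size must be >= 0")
        if self.redundancy * self.n_go > self.n_taxa:
            raise SimConfigError(
                "redundancy * n_go exceeds n_taxa: the taxon->GO map is "
                "injective by group and cannot be built"
            )

    def env_variable_names(self) -> list[str]:
        if self.n_env == len(ENV_VARIABLES):
            return list(ENV_VARIABLES)
        return [f"env{i + 1:02d}" for i in range(self.n_env)]

    def env_blocks(self) -> tuple[list[str], list[str]]:
        """The two collinear variable blocks (particulate-like, dissolved-like)."""
        names = self.env_variable_names()
        if self.n_env == len(ENV_VARIABLES):
            return list(PARTICULATE_BLOCK), list(DISSOLVED_BLOCK)
        half = max(1, self.n_env // 2)
        return names[:half], names[half:]


@dataclass
class GroundTruth:
    """What was planted: indicator identities, slopes, map, carriers."""

    taxon_to_go: pd.Series                 # taxon id -> GO id (NaN if unmapped)
    indicator_go: list                     # GO ids with a planted association
    go_env_variable: pd.Series             # GO id -> designated env variable
    go_slope: pd.Series                    # GO id -> planted slope (0 if none)
    preferred_carriers: pd.DataFrame       # trips x indicator GO: trip-preferred member
    site_carriers: pd.DataFrame            # sites x indicator GO: realized dominant member
    trip_batch_sd: float

    @property
    def indicator_taxa(self) -> list:
        """All member taxa of planted GO groups (each inherits the signal)."""
        members = self.taxon_to_go[self.taxon_to_go.isin(self.indicator_go)]
        return list(members.index)


@dataclass
class SyntheticDataset:
    taxa_counts: CountTable
    go_counts: CountTable
    env: EnvTable
    truth: GroundTruth
    config: SimConfig


def _taxon_lineage(order: np.ndarray) -> pd.DataFrame:
    """Nested lineage labels from a shuffled placement of genera."""
    fam = order // 3
    ordr = fam // 4
    cls = ordr // 4
    phy = cls // 3
    return pd.DataFrame({
        "domain": "Bacteria",
        "phylum": [f"p__P{v:02d}" for v in phy],
        "class": [f"c__C{v:03d}" for v in cls],
        "order": [f"o__O{v:03d}" for v in ordr],
        "family": [f"f__F{v:03d}" for v in fam],
    })


def generate(config: SimConfig) -> SyntheticDataset:
    """Draw one synthetic taxa/GO/environment dataset.

    Deterministic given ``config.seed``; see the module docstring for the
    generative model.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.n_trips * cfg.sites_per_trip
    n_samples = n_sites * cfg.replicates_per_site
    trips = [f"T{t + 1}" for t in range(cfg.n_trips)]

    # --- sites & coordinates: trips occupy latitudinal bands along the reef,
    # confounding season with geography as in the surveyed design
    site_ids = [f"R{i + 1:03d}" for i in range(n_sites)]
    site_trip_idx = np.repeat(np.arange(cfg.n_trips), cfg.sites_per_trip)
    band_centers = np.linspace(-15.0, -22.0, cfg.n_trips)
    lat = band_centers[site_trip_idx] + rng.uniform(-1.0, 1.0, n_sites)
    lon = 145.3 + 0.38 * (-lat - 14.0) + rng.uniform(-0.4, 0.4, n_sites)

    # --- environment: two collinear blocks + per-trip seasonal block shifts
    var_names = cfg.env_variable_names()
    block1, block2 = cfg.env_blocks()
    z = rng.standard_normal((n_sites, cfg.n_env))
    rho = cfg.env_block_cor
    for block in (block1, block2):
        idx = [var_names.index(v) for v in block]
        factor = rng.standard_normal(n_sites)
        z[:, idx] = np.sqrt(rho) * factor[:, None] + np.sqrt(1 - rho) * z[:, idx]
    for block in (block1, block2):  # seasonal shift shared within a block
        idx = [var_names.index(v) for v in block]
        shift = rng.normal(0.0, cfg.env_trip_sd, cfg.n_trips)
        z[:, idx] += shift[site_trip_idx][:, None]
    z += rng.normal(0.0, 0.3 * cfg.env_trip_sd,
                    (cfg.n_trips, cfg.n_env))[site_trip_idx]
    # standardize so planted slopes are per overall SD of each variable
    z_std = (z - z.mean(axis=0)) / z.std(axis=0, ddof=0)

    env_values = np.empty_like(z_std)
    for j, name in enumerate(var_names):
        loc, scale = _ENV_SCALES.get(name, (10.0, 1.0))
        env_values[:, j] = loc + scale * z_std[:, j]
    env_values = np.clip(env_values, 0.0, None)
    env = EnvTable(
        values=pd.DataFrame(env_values, index=pd.Index(site_ids, name="site"),
                            columns=var_names),
        trips=pd.Series([trips[t] for t in site_trip_idx],
                        index=pd.Index(site_ids, name="site"), name="trip"),
    )

    # --- taxon -> GO map: contiguous groups of `redundancy` member taxa;
    # any surplus taxa beyond redundancy*n_go are unmapped singletons
    taxa_ids = [f"g__G{i + 1:04d}" for i in range(cfg.n_taxa)]
    go_ids = [f"GO:{7000000 + i + 1}" for i in range(cfg.n_go)]
    n_mapped = cfg.redundancy * cfg.n_go
    n_extra = cfg.n_taxa - n_mapped
    taxon_to_go = pd.Series(
        [go_ids[i // cfg.redundancy] if i < n_mapped else np.nan
         for i in range(cfg.n_taxa)],
        index=pd.Index(taxa_ids, name="feature_id"), name="go_id",
    )

    # --- planted indicators: designated variables cycle through the
    # productivity (particulate + chlorophyll) block unless overridden
    indicator_pos = np.sort(rng.choice(cfg.n_go, cfg.n_indicator_go, replace=False))
    indicator_go = [go_ids[g] for g in indicator_pos]
    if cfg.indicator_env_vars is None:
        driver_pool = block1
    else:
        driver_pool = [v if isinstance(v, str) else var_names[v]
                       for v in cfg.indicator_env_vars]
    go_env = pd.Series(index=pd.Index(go_ids, name="feature_id"), dtype=object)
    go_slope = pd.Series(0.0, index=pd.Index(go_ids, name="feature_id"))
    for j, g in enumerate(indicator_pos):
        go_env.iloc[g] = driver_pool[j % len(driver_pool)]
        go_slope.iloc[g] = cfg.effect_size

    # --- trip-preferred carriers (rotated across trips) and per-site dominants
    group_phase = rng.integers(0, cfg.redundancy, cfg.n_go)
    preferred = pd.DataFrame(index=pd.Index(trips, name="trip"),
                             columns=go_ids, dtype=object)
    for t in range(cfg.n_trips):
        for g in range(cfg.n_go):
            member = (group_phase[g] + t) % cfg.redundancy
            preferred.iloc[t, g] = taxa_ids[g * cfg.redundancy + member]
    dominant_member = np.empty((n_sites, cfg.n_go), dtype=np.int64)
    for s in range(n_sites):
        t = site_trip_idx[s]
        for g in range(cfg.n_go):
            pref = (group_phase[g] + t) % cfg.redundancy
            if cfg.redundancy == 1 or rng.random() < cfg.carrier_fidelity:
                dominant_member[s, g] = pref
            else:
                others = [m for m in range(cfg.redundancy) if m != pref]
                dominant_member[s, g] = others[rng.integers(len(others))]
    site_carriers = pd.DataFrame(
        [[taxa_ids[g * cfg.redundancy + dominant_member[s, g]]
          for g in indicator_pos]
         for s in range(n_sites)],
        index=pd.Index(site_ids, name="site"), columns=indicator_go,
    )

    # --- group-level latents (GO groups + unmapped singleton taxa)
    n_groups = cfg.n_go + n_extra
    base = rng.normal(0.0, cfg.base_abundance_sd, n_groups)
    batch = rng.normal(0.0, cfg.batch_sd, (cfg.n_trips, n_groups))
    sample_trip_idx = np.repeat(site_trip_idx, cfg.replicates_per_site)
    sample_site_idx = np.repeat(np.arange(n_sites), cfg.replicates_per_site)
    sample_ids = [
        f"{trips[sample_trip_idx[s]]}-{site_ids[sample_site_idx[s]]}-"
        f"r{s % cfg.replicates_per_site + 1}"
        for s in range(n_samples)
    ]
    group_latent = base[None, :] + batch[sample_trip_idx, :]
    var_col = {v: j for j, v in enumerate(var_names)}
    for j, g in enumerate(indicator_pos):
        j_env = var_col[go_env.iloc[g]]
        group_latent[:, g] += cfg.effect_size * z_std[sample_site_idx, j_env]
    group_latent += rng.normal(0.0, cfg.feature_noise_sd, (n_samples, n_groups))

    # --- membership log-weights within each GO group
    member_base = rng.normal(0.0, cfg.member_base_sd, (cfg.n_go, cfg.redundancy))
    logw = np.broadcast_to(member_base, (n_samples, cfg.n_go, cfg.redundancy)).copy()
    boost = np.zeros((n_sites, cfg.n_go, cfg.redundancy))
    np.put_along_axis(boost, dominant_member[:, :, None], cfg.carrier_boost, axis=2)
    logw += boost[sample_site_idx]
    logw += rng.normal(0.0, cfg.member_noise_sd, logw.shape)

    # --- probabilities and counts (single multinomial over taxa per sample)
    gl = group_latent - group_latent.max(axis=1, keepdims=True)
    pg = np.exp(gl)
    pg /= pg.sum(axis=1, keepdims=True)
    wm = np.exp(logw - logw.max(axis=2, keepdims=True))
    wm /= wm.sum(axis=2, keepdims=True)
    p_taxa = np.empty((n_samples, cfg.n_taxa))
    p_taxa[:, :n_mapped] = (pg[:, :cfg.n_go, None] * wm).reshape(n_samples, n_mapped)
    if n_extra:
        p_taxa[:, n_mapped:] = pg[:, cfg.n_go:]

    lib = np.maximum(rng.poisson(cfg.library_size_mean, n_samples), 1)
    counts = np.empty((n_samples, cfg.n_taxa), dtype=np.int64)
    for s in range(n_samples):
        counts[s] = rng.multinomial(lib[s], p_taxa[s] / p_taxa[s].sum())
    go_counts = counts[:, :n_mapped].reshape(
        n_samples, cfg.n_go, cfg.redundancy).sum(axis=2)

    # --- assemble containers
    samples = pd.DataFrame({
        "trip": [trips[t] for t in sample_trip_idx],
        "site": [site_ids[i] for i in sample_site_idx],
        "replicate": [s % cfg.replicates_per_site + 1 for s in range(n_samples)],
        "lat": lat[sample_site_idx],
        "lon": lon[sample_site_idx],
    }, index=pd.Index(sample_ids, name="sample_id"))

    lineage = _taxon_lineage(rng.permutation(cfg.n_taxa))
    taxa_features = lineage.assign(genus=taxa_ids)
    taxa_features.index = pd.Index(taxa_ids, name="feature_id")
    taxa_features.insert(0, "annotation", "bacteria")

    go_features = pd.DataFrame({
        "annotation": "bacteria",
        "rank3": [f"GO3:{i // 9 + 1:03d}" for i in range(cfg.n_go)],
        "rank4": [f"GO4:{i // 3 + 1:03d}" for i in range(cfg.n_go)],
        "rank5": go_ids,
    }, index=pd.Index(go_ids, name="feature_id"))

    taxa_table = CountTable(
        counts=pd.DataFrame(counts, index=samples.index, columns=taxa_ids),
        samples=samples, features=taxa_features,
    )
    go_table = CountTable(
        counts=pd.DataFrame(go_counts, index=samples.index, columns=go_ids),
        samples=samples, features=go_features,
    )
    truth = GroundTruth(
        taxon_to_go=taxon_to_go, indicator_go=indicator_go,
        go_env_variable=go_env, go_slope=go_slope,
        preferred_carriers=preferred[indicator_go],
        site_carriers=site_carriers,
        trip_batch_sd=cfg.batch_sd,
    )
    return SyntheticDataset(taxa_counts=taxa_table, go_counts=go_table,
                            env=env, truth=truth, config=cfg)


def write_dataset(ds: SyntheticDataset, directory) -> dict:
    """Write a dataset as plain TSV files; returns the manifest.

    Count tables are written features x samples.  ``truth.tsv`` records, per
    feature, the planted slope (``effect_size`` for indicator GO terms and
    their member taxa, 0 otherwise), the designated environment variable and
    the GO group; trip-preferred carriers go to ``truth_carriers.tsv``.
    """
    from . import io as _io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": {}}

    def record(name: str, n_rows: int, n_cols: int) -> None:
        manifest["files"][name] = {"rows": int(n_rows), "columns": int(n_cols)}

    _io.write_count_table(ds.taxa_counts, directory / "taxa_counts.tsv",
                          directory / "taxa_features.tsv")
    record("taxa_counts.tsv", *ds.taxa_counts.counts.shape[::-1])
    record("taxa_features.tsv", len(ds.taxa_counts.features),
           len(ds.taxa_counts.features.columns))
    _io.write_count_table(ds.go_counts, directory / "go_counts.tsv",
                          directory / "go_features.tsv")
    record("go_counts.tsv", *ds.go_counts.counts.shape[::-1])
    record("go_features.tsv", len(ds.go_counts.features),
           len(ds.go_counts.features.columns))

    ds.taxa_counts.samples.to_csv(directory / "samples.tsv", sep="\t")
    record("samples.tsv", *ds.taxa_counts.samples.shape)
    _io.write_env_table(ds.env, directory / "env.tsv")
    record("env.tsv", len(ds.env.values), len(ds.env.variables) + 1)

    indicator_members = set(ds.truth.indicator_taxa)
    member_env = {}
    for go_id in ds.truth.indicator_go:
        for taxon in ds.truth.taxon_to_go.index[ds.truth.taxon_to_go == go_id]:
            member_env[taxon] = ds.truth.go_env_variable.loc[go_id]
    truth_rows = []
    for go_id in ds.truth.go_slope.index:
        env_var = ds.truth.go_env_variable.get(go_id)
        truth_rows.append({
            "feature_id": go_id, "table": "go", "go_group": go_id,
            "env_variable": env_var if isinstance(env_var, str) else "",
            "slope": float(ds.truth.go_slope.loc[go_id]),
        })
    for taxon, go_id in ds.truth.taxon_to_go.items():
        planted = taxon in indicator_members
        truth_rows.append({
            "feature_id": taxon, "table": "taxa",
            "go_group": go_id if isinstance(go_id, str) else "",
            "env_variable": member_env.get(taxon, ""),
            "slope": float(ds.config.effect_size) if planted else 0.0,
        })
    truth_df = pd.DataFrame(truth_rows)
    truth_df.to_csv(directory / "truth.tsv", sep="\t", index=False)
    record("truth.tsv", len(truth_df), len(truth_df.columns))

    ds.truth.preferred_carriers.to_csv(directory / "truth_carriers.tsv", sep="\t")
    record("truth_carriers.tsv", *ds.truth.preferred_carriers.shape)

    manifest["config"] = asdict(ds.config)
    if manifest["config"]["indicator_env_vars"] is not None:
        manifest["config"]["indicator_env_vars"] = list(
            manifest["config"]["indicator_env_vars"])
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
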