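"""In-memory containers shared across the pipeline.

All tabular data lives in pandas DataFrames; the dataclasses below only add
the metadata that keeps count matrices, sample sheets and feature annotations
aligned, and validate the invariants each stage relies on (non-negative
integer counts, unique ids, one environment row per reef site).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: annotation classes removed by the post-annotation filter
EXCLUDED_CLASSES = frozenset({"unannotated", "eukaryote", "virus", "domain_only"})

SAMPLE_COLUMNS = ("trip", "site", "replicate", "lat", "lon")


class ValidationError(ValueError):
    """Raised when a container violates one of its structural invariants."""


@dataclass
class CountTable:
    """A sample x feature count matrix with sample and feature metadata.

    Parameters
    ----------
    counts : DataFrame
        Non-negative integer matrix, rows indexed by sample id, columns by
        feature id.
    samples : DataFrame
        One row per sample (trip, site, replicate, lat, lon).
    features : DataFrame
        One row per feature; must contain an ``annotation`` column (the
        annotation class) plus one column per hierarchical rank, coarse to fine
        (e.g. domain..genus for taxa, rank3..rank5 for GO terms).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        if self.counts.columns.has_duplicates:
            raise ValidationError("duplicate feature ids in count matrix")
        arr = self.counts.to_numpy()
        if arr.size and arr.min() < 0:
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.counts.index[i]!r}, "
                f"feature {self.counts.columns[j]!r}"
            )
        missing_meta = self.counts.index.difference(self.samples.index)
        if len(missing_meta):
            raise ValidationError(f"samples missing metadata: {list(missing_meta)[:5]}")
        self.samples = self.samples.loc[self.counts.index]
        unknown = self.counts.columns.difference(self.features.index)
        if len(unknown):
            # unknown features default to 'unannotated' (filter rule 1 removes them)
            warnings.warn(
                f"{len(unknown)} features missing annotation; classed 'unannotated'",
                stacklevel=2,
            )
            extra = pd.DataFrame(index=unknown, columns=self.features.columns)
            self.features = pd.concat([self.features, extra])
        self.features = self.features.loc[self.counts.columns]
        if "annotation" not in self.features.columns:
            self.features["annotation"] = "unannotated"
        self.features["annotation"] = self.features["annotation"].fillna("unannotated")

    # -- convenience accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def rank_names(self) -> list[str]:
        """Hierarchical rank columns, coarse to fine."""
        return [c for c in self.features.columns if c != "annotation"]

    def restrict_samples(self, sample_ids) -> "CountTable":
        return CountTable(
            self.counts.loc[sample_ids], self.samples.loc[sample_ids], self.features
        )

    def restrict_features(self, feature_ids) -> "CountTable":
        return CountTable(
            self.counts.loc[:, feature_ids], self.samples, self.features.loc[feature_ids]
        )


@dataclass
class EnvTable:
    """Reef-site x physico-chemical variable table (one row per trip/site).

    ``values`` is indexed by site id; ``trips`` maps each site to the trip on
    which it was sampled (sites are visited on exactly one trip).  Missing
    measurements are NaN and are excluded pairwise downstream.
    """

    values: pd.DataFrame
    trips: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate site rows in environment table")
        missing = self.values.index.difference(self.trips.index)
        if len(missing):
            raise ValidationError(f"sites missing a trip assignment: {list(missing)[:5]}")
        self.trips = self.trips.loc[self.values.index]

    @property
    def variables(self) -> pd.Index:
        return self.values.columns

    @property
    def sites(self) -> pd.Index:
        return self.values.index

    def for_samples(self, samples: pd.DataFrame) -> pd.DataFrame:
        """Repeat each site's environment row across that site's samples."""
        missing = pd.Index(samples["site"].unique()).difference(self.values.index)
        if len(missing):
            raise ValidationError(f"samples reference unknown sites: {list(missing)[:5]}")
        out = self.values.loc[samples["site"]]
        out.index = samples.index
        return out


@dataclass
class ClrMatrix:
    """Centered log-ratio transformed abundances (rows sum to zero)."""

    values: pd.DataFrame
    pseudocount: float
    source: str = ""

    def __post_init__(self) -> None:
        rs = self.values.to_numpy().sum(axis=1)
        if rs.size and np.abs(rs).max() > 1e-9 * max(1, self.values.shape[1]):
            raise ValidationError("CLR rows must sum to zero")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with a metric label."""

    values: pd.DataFrame
    metric: str

    def __post_init__(self) -> None:
        a = self.values.to_numpy()
        if a.shape[0] != a.shape[1]:
            raise ValidationError("distance matrix must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if a.size and np.abs(np.diag(a)).max() > 0:
            raise ValidationError("distance matrix diagonal must be zero")
        if a.size and a.min() < 0:
            raise ValidationError("distances must be non-negative")
        if self.metric == "braycurtis" and a.size and a.max() > 1 + 1e-12:
            raise ValidationError("Bray-Curtis entries must lie in [0, 1]")

    @property
    def ids(self) -> pd.Index:
        return self.values.index

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in scipy condensed order."""
        a = self.values.to_numpy()
        iu = np.triu_indices(a.shape[0], k=1)
        return a[iu]
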