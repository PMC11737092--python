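"""TSV readers/writers for count tables, metadata and environment tables.

Dialect: UTF-8, tab-separated, '.' decimal, header row mandatory.  Count
tables are stored features x samples (features as rows) with the feature id
in the first column; the feature annotation TSV is keyed by feature id and
carries the annotation class plus one column per hierarchical rank.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountTable, EnvTable, ValidationError


class IOError_(ValueError):
    """User-facing input error (malformed file, inconsistent ids)."""


def read_count_table(counts_path, samples_path, features_path=None) -> CountTable:
    """Read a features x samples count TSV plus sample (and feature) metadata.

    Non-integer or negative cells raise an error naming the offending
    feature/sample; features absent from the annotation are classed
    ``unannotated`` (and will be dropped by filter rule 1).
    """
    raw = pd.read_csv(counts_path, sep="\t", index_col=0)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise IOError_(f"duplicate feature id {dup!r} in {counts_path}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise IOError_(f"duplicate sample id {dup!r} in {counts_path}")
    arr = raw.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = raw.columns[[not np.issubdtype(t, np.number) for t in raw.dtypes]][0]
        raise IOError_(f"non-numeric cells in sample column {bad!r}")
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise IOError_(
            f"non-integer count at feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if (arr < 0).any():
        i, j = np.argwhere(arr < 0)[0]
        raise IOError_(
            f"negative count at feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    counts = raw.T.astype(np.int64)
    counts.index.name = "sample_id"

    samples = pd.read_csv(samples_path, sep="\t", index_col=0)
    missing = counts.index.difference(samples.index)
    if len(missing):
        raise IOError_(f"samples missing metadata: {list(missing)[:5]}")

    if features_path is not None and Path(features_path).exists():
        features = pd.read_csv(features_path, sep="\t", index_col=0, dtype=str)
        unknown = features.index.difference(counts.columns)
        if len(unknown):
            warnings.warn(
                f"{len(unknown)} annotated features absent from counts; ignored",
                stacklevel=2,
            )
            features = features.loc[features.index.intersection(counts.columns)]
    else:
        features = pd.DataFrame(index=counts.columns.copy())
        features["annotation"] = "unannotated"
    try:
        return CountTable(counts=counts, samples=samples.loc[counts.index],
                          features=features)
    except ValidationError as exc:
        raise IOError_(str(exc)) from exc


def write_count_table(t: CountTable, counts_path, features_path=None) -> None:
    out = t.counts.T
    out.index.name = "feature_id"
    out.to_csv(counts_path, sep="\t")
    if features_path is not None:
        t.features.rename_axis("feature_id").to_csv(features_path, sep="\t")


def read_env_table(path) -> EnvTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "trip" not in df.columns:
        raise IOError_(f"environment table {path} needs a 'trip' column")
    trips = df["trip"].astype(str)
    values = df.drop(columns=["trip"]).astype(float)
    return EnvTable(values=values, trips=trips)


def write_env_table(e: EnvTable, path) -> None:
    out = e.values.copy()
    out.insert(0, "trip", e.trips)
    out.rename_axis("site").to_csv(path, sep="\t")


def read_dataset(directory) -> tuple[CountTable, CountTable, EnvTable]:
    """Read the (taxa, go, env) trio written by ``simulate.write_dataset``."""
    directory = Path(directory)
    taxa = read_count_table(directory / "taxa_counts.tsv",
                            directory / "samples.tsv",
                            directory / "taxa_features.tsv")
    go = read_count_table(directory / "go_counts.tsv",
                          directory / "samples.tsv",
                          directory / "go_features.tsv")
    env = read_env_table(directory / "env.tsv")
    return taxa, go, env
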