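import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from reefpls import CountTable, SimConfig, generate

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_dataset():
    """One draw at the full survey design (4 trips x 12 sites x 4 replicates)."""
    return generate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down design for fast multi-seed checks."""
    return SimConfig(seed=0, sites_per_trip=6, n_taxa=120, n_go=30,
                     n_indicator_go=10, library_size_mean=20_000.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config)


def toy_count_table(counts, lineages=None, annotation="bacteria",
                    n_trips=1, sites=None):
    """Build a CountTable from a plain array with minimal metadata."""
    counts = np.asarray(counts)
    n, p = counts.shape
    sample_ids = [f"s{i}" for i in range(n)]
    feature_ids = [f"f{j}" for j in range(p)]
    sites = sites or [f"site{i % max(1, n // 2)}" for i in range(n)]
    samples = pd.DataFrame({
        "trip": [f"T{i % n_trips + 1}" for i in range(n)],
        "site": sites,
        "replicate": list(range(1, n + 1)),
        "lat": -18.0, "lon": 147.0,
    }, index=pd.Index(sample_ids, name="sample_id"))
    feats = {"annotation": (annotation if isinstance(annotation, list)
                            else [annotation] * p)}
    if lineages is not None:
        for rank, labels in lineages.items():
            feats[rank] = labels
    features = pd.DataFrame(feats, index=pd.Index(feature_ids, name="feature_id"))
    return CountTable(
        counts=pd.DataFrame(counts, index=samples.index, columns=feature_ids),
        samples=samples, features=features,
    )
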