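import numpy as np
import pandas as pd
import pytest

from microstab import (FeatureTable, SampleMetadata, SimulationConfig,
                       simulate_study)


@pytest.fixture
def small_counts() -> FeatureTable:
    data = pd.DataFrame(
        [[3, 0, 5, 1],
         [1, 2, 0, 4],
         [0, 6, 2, 0],
         [2, 2, 1, 1],
         [4, 0, 0, 3]],
        index=[f"f{i}" for i in range(1, 6)],
        columns=[f"s{i}" for i in range(1, 5)],
        dtype=float,
    )
    return FeatureTable(data)


def make_metadata(rows: list[dict]) -> SampleMetadata:
    frame = pd.DataFrame(rows).set_index("sample_id")
    return SampleMetadata(frame)


@pytest.fixture
def factorial_metadata() -> SampleMetadata:
    rows = []
    for treat in ("control", "nutrient"):
        for tp in ("T1", "T2"):
            for rep in ("r1", "r2"):
                rows.append({
                    "sample_id": f"endo.{treat}.{tp}.{rep}",
                    "niche": "endo", "treatment": treat, "timepoint": tp,
                    "experiment": "e1", "replicate": rep,
                })
    return make_metadata(rows)


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared by read-only tests."""
    cfg = SimulationConfig(n_features_per_niche=120, niches=("endo", "epi"),
                           depth_mean=4000, depth_dispersion=0.3,
                           effect_size=2.5, recovery=0.5, seed=42)
    return simulate_study(cfg)


def random_counts_table(rng: np.random.Generator, n_features: int = 12,
                        n_samples: int = 6, max_count: int = 50) -> FeatureTable:
    data = rng.integers(0, max_count, size=(n_features, n_samples)).astype(float)
    # avoid all-zero samples
    data[rng.integers(0, n_features), :] += 1
    return FeatureTable(pd.DataFrame(
        data,
        index=[f"f{i}" for i in range(n_features)],
        columns=[f"s{i}" for i in range(n_samples)],
    ))
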