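import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clusterhet as ch

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def moderate_dataset() -> ch.ClusteredBinaryDataset:
    """One moderately sized simulated dataset reused across fit tests."""
    cfg = ch.SimulationConfig(n_clusters=60, cluster_size=25, sigma2_u=0.5, seed=7)
    return ch.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def moderate_fit(moderate_dataset):
    return ch.fit(moderate_dataset)


def tiny_datasets() -> list[ch.ClusteredBinaryDataset]:
    """Five tiny datasets (2-4 clusters, <= 5 obs each) for oracle checks."""
    out = []
    # seeds chosen so each tiny dataset has both outcome classes, a varying
    # cluster covariate, and a finite interior-or-boundary ML optimum
    rng_specs = [
        (2, 3, 0.4, 102),
        (3, 4, 0.8, 202),
        (4, 5, 0.2, 303),
        (2, 5, 1.0, 112),
        (3, 3, 0.6, 113),
    ]
    for H, N, s2, seed in rng_specs:
        cfg = ch.SimulationConfig(n_clusters=H, cluster_size=N, sigma2_u=s2,
                                  beta0=0.3, beta1=-0.8, beta2=0.2, alpha=-0.3,
                                  seed=seed)
        out.append(ch.simulate_dataset(cfg))
    return out


@pytest.fixture(scope="session")
def small_grid_summaries():
    """A tiny but complete grid run, shared by study-module tests."""
    spec = ch.GridSpec(
        cluster_counts=(10, 20),
        cluster_sizes=(5, 10),
        variances=(0.2, 0.5),
        replicates=3,
        base_seed=42,
    )
    return spec, ch.run_grid(spec)


def assert_dirs_byte_identical(dir_a, dir_b, pattern="*.csv"):
    names_a = sorted(p.name for p in dir_a.glob(pattern))
    names_b = sorted(p.name for p in dir_b.glob(pattern))
    assert names_a == names_b and names_a
    for name in names_a:
        assert (dir_a / name).read_bytes() == (dir_b / name).read_bytes(), name
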