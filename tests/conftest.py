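"""Shared fixtures: small synthetic datasets with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from islandclock import SimulationTruth, simulate_dataset


def two_tissue_truth(seed: int, noise_sd: float = 0.3, **overrides) -> SimulationTruth:
    """A fast two-tissue instance for unit tests."""
    kwargs = dict(
        n_cpgs=300,
        n_shared_age_cpgs=10,
        n_specific_age_cpgs_per_tissue=3,
        n_identity_cpgs=30,
        tissue_sizes={"a": 60, "b": 40},
        age_ranges={"a": (25.0, 85.0), "b": (30.0, 75.0)},
        noise_sd=noise_sd,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationTruth(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    """Two-tissue dataset with moderate noise (seed 7)."""
    return simulate_dataset(two_tissue_truth(seed=7))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Two-tissue dataset with no noise: planted signal is exact."""
    return simulate_dataset(two_tissue_truth(seed=3, noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
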