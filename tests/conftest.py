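"""Shared fixtures: small synthetic datasets and a mid-sized decoding set.

Expensive fixtures are session-scoped; tests never mutate them.
"""

from __future__ import annotations

import pytest
from hypothesis import settings

import spikeloc as sl

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def tiny_config() -> sl.SyntheticConfig:
    """4 structures (one per region), short session: fast IO/filter tests."""
    structures = tuple(
        sp for sp in sl.synth.default_structure_params()
        if sp.structure in ("CA1", "LGd", "VISp", "MB")
    )
    return sl.SyntheticConfig(
        n_animals=3,
        structures=structures,
        units_per_structure=12,
        gratings_repeats=2,
        movie_duration_s=120.0,
        spontaneous_duration_s=120.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config) -> sl.Dataset:
    return sl.simulate_dataset(tiny_config)


@pytest.fixture(scope="session")
def small_config() -> sl.SyntheticConfig:
    """All 12 structures, 6 animals, 1/3-length gratings block."""
    return sl.SyntheticConfig(
        n_animals=6,
        units_per_structure=36,
        gratings_repeats=5,
        movie_duration_s=240.0,
        spontaneous_duration_s=240.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> sl.Dataset:
    return sl.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def decoding_dataset() -> sl.Dataset:
    """Mid-sized separable dataset for decoding tests: full gratings block."""
    cfg = sl.SyntheticConfig(
        n_animals=8,
        units_per_structure=60,
        gratings_repeats=15,
        movie_duration_s=0.0,
        spontaneous_duration_s=300.0,
        seed=21,
    )
    return sl.simulate_dataset(cfg)
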