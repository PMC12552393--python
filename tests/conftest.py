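"""Shared fixtures: scaled-down simulated datasets and toy matrices."""

import dataclasses

import pandas as pd
import pytest

from epiradkit.simdata import SimConfig, simulate_dataset


def small_config(**overrides) -> SimConfig:
    """Default design (32 individuals) at reduced loci/depth for fast tests.

    Depth per locus stays high enough (~500x) that random EpiRAD dropout of
    unmethylated retained loci is negligible.
    """
    base = dict(
        n_loci=600,
        mean_library_size_rad=3.0e5,
        mean_library_size_epirad=3.5e5,
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(small_config(seed=11))


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=3)


@pytest.fixture()
def toy_calls():
    """4 loci x 3 samples; rows 3 and 4 are differential."""
    return pd.DataFrame(
        [[0, 0, 0], [1, 1, 1], [0, 1, 0], [1, 0, 1]],
        index=["L1", "L2", "L3", "L4"],
        columns=["s1", "s2", "s3"],
    )


def replace(cfg: SimConfig, **kw) -> SimConfig:
    return dataclasses.replace(cfg, **kw)
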