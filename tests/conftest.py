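import dataclasses

import numpy as np
import pandas as pd
import pytest

from serasim import SimConfig, default_species
from serasim.params import SpeciesParams


@pytest.fixture(scope="session")
def species():
    return default_species()


@pytest.fixture(scope="session")
def abies(species):
    return species["abies_alba"]


@pytest.fixture()
def tiny_config():
    """A 10-stem, 3-year scenario for fast structural tests."""
    return SimConfig(species="abies_alba", planting_density=10,
                     area_ha=1.0, years=3, rng_seed=42)


@pytest.fixture(scope="session")
def fast_species(species):
    """Species tuned for quick small-stand tests (unchanged biology)."""
    return {k: dataclasses.replace(v) for k, v in species.items()}


def make_table(heights, dbhs=None, **extra):
    """Small stem-table helper used across metric tests."""
    heights = np.asarray(heights, dtype=float)
    if dbhs is None:
        dbhs = heights / 100.0
    df = pd.DataFrame({
        "tree_id": np.arange(len(heights)),
        "height_m": heights,
        "dbh_m": np.asarray(dbhs, dtype=float),
    })
    for k, v in extra.items():
        df[k] = v
    return df
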