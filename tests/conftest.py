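import warnings

import numpy as np
import pandas as pd
import pytest

from betashift.io import (
    AssemblageMatrix,
    TraitTable,
    align_periods,
)
from betashift.synthetic import SyntheticScenario, generate_dataset


def make_matrix(rows: dict, species: list, period="") -> AssemblageMatrix:
    """Build an AssemblageMatrix from {site: [present species]}."""
    data = pd.DataFrame(
        [[1 if sp in present else 0 for sp in species]
         for present in rows.values()],
        index=list(rows), columns=species,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return AssemblageMatrix(data, period)


@pytest.fixture
def tiny_traits():
    species = [f"s{i}" for i in range(1, 7)]
    data = pd.DataFrame({
        "life_form": ["submerged", "submerged", "emergent", "floating_leaved",
                      "free_floating", "emergent"],
        "life_cycle": ["annual", "perennial", "perennial", "annual",
                       "perennial", "annual"],
        "morphology": ["stem", "rosette", "leafy", "turion", "stem", "leafy"],
        "dispersal_range": ["cosmopolitan", "local", "regional",
                            "asian_endemic", "cosmopolitan", "local"],
        "sexual_propagation": ["monoecism", "dioecy", "monoecism", "dioecy",
                               "monoecism", "monoecism"],
    }, index=species)
    return TraitTable(data)


@pytest.fixture
def tiny_paired():
    species = [f"s{i}" for i in range(1, 7)]
    hist = make_matrix(
        {"L1": ["s1", "s2", "s3", "s4"],
         "L2": ["s2", "s3", "s5", "s6"],
         "L3": ["s1", "s3", "s4", "s5", "s6"]},
        species, "historical")
    curr = make_matrix(
        {"L1": ["s1", "s2"],
         "L2": ["s2", "s3", "s5"],
         "L3": ["s1", "s3", "s4"]},
        species, "current")
    return align_periods(hist, curr)


@pytest.fixture(scope="session")
def small_dataset():
    """A 12-site, 60-species synthetic dataset shared across tests."""
    scenario = SyntheticScenario(n_sites=12, pool_size=60, mean_richness=20,
                                 seed=101)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_dataset(scenario)


@pytest.fixture(autouse=True)
def _quiet_empty_site_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*sites with no species.*")
        warnings.filterwarnings(
            "ignore", message=".*sites empty in at least one period.*")
        yield
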