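import numpy as np
import pytest

from fuzzysdm import (
    EnvGrid,
    MembershipSurface,
    TrueSpecies,
    make_env_grid,
    sample_background,
    sample_occurrences,
    true_probability_surface,
)
from fuzzysdm.sdm import ModelTable, build_table


def random_surface(rng, shape=(4, 5), kind="favourability"):
    """Small random membership surface (no nodata)."""
    return MembershipSurface(values=rng.random(shape), kind=kind)


@pytest.fixture(scope="session")
def small_grid():
    return make_env_grid(seed=11, n_rows=30, n_cols=30, n_layers=3, smoothness=4.0)


@pytest.fixture(scope="session")
def linear_species():
    return TrueSpecies("lin", intercept=-1.0, coefficients={"env1": 2.0, "env2": 1.0})


@pytest.fixture(scope="session")
def small_study(small_grid, linear_species):
    """Grid, species, presences, background, and the extracted model table."""
    p = true_probability_surface(small_grid, linear_species)
    occ = sample_occurrences(p, 120, seed=5)
    bg = sample_background(small_grid, 600, seed=6)
    table = build_table(small_grid, occ, bg)
    return small_grid, linear_species, occ, bg, table
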