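"""Shared fixtures: small grids, tiny cohorts, and a mini trained model.

Heavyweight cohort/model fixtures used by the acceptance tests live in
``test_acceptance.py`` (module scope) so that unit tests stay fast.
"""

import numpy as np
import pytest

from fetalfrac.grids import make_bin_grid
from fetalfrac.profiles import CopyNumberProfile
from fetalfrac.simulate import SimulationParams, simulate_cohort


@pytest.fixture(scope="session")
def small_grid():
    """Two tiny autosomes plus X and Y (30 bins at 100 kb)."""
    return make_bin_grid(
        {"1": 1_000_000, "2": 800_000, "X": 800_000, "Y": 400_000}, 100_000
    )


@pytest.fixture()
def flat_profile(small_grid):
    return CopyNumberProfile("flat", small_grid,
                             np.zeros(small_grid.n_bins), sex_label="female")


@pytest.fixture(scope="session")
def mini_params():
    """Small, fast cohort world shared by several unit tests."""
    return SimulationParams(n_samples=120, seed=5)


@pytest.fixture(scope="session")
def mini_cohort(mini_params):
    return simulate_cohort(mini_params)
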