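"""Shared fixtures: synthetic study pieces reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from lipidqens.fitting import headgroup_protocol
from lipidqens.synthetic import (
    default_ground_truth,
    default_q_grid,
    generate_qens_dataset,
    generate_resolution,
)


@pytest.fixture(scope="session")
def q_grid():
    return default_q_grid()


@pytest.fixture(scope="session")
def resolutions(q_grid):
    return {
        "high_intensity": generate_resolution("high_intensity", q_grid),
        "high_resolution": generate_resolution("high_resolution", q_grid),
    }


@pytest.fixture(scope="session")
def truth():
    return default_ground_truth(seed=42)


@pytest.fixture(scope="session")
def headgroup_pair_358(truth, q_grid, resolutions):
    """Seeded Poisson-noise headgroup spectra, both modes, 358 K."""
    data = generate_qens_dataset(
        truth,
        design=[
            ("headgroup_only", "high_intensity", 358.0),
            ("headgroup_only", "high_resolution", 358.0),
        ],
        q_values=q_grid,
        resolutions=resolutions,
    )
    return (
        data[("headgroup_only", "high_intensity", 358.0)],
        data[("headgroup_only", "high_resolution", 358.0)],
    )


@pytest.fixture(scope="session")
def headgroup_result_358(headgroup_pair_358, resolutions):
    hi, hr = headgroup_pair_358
    return headgroup_protocol(
        hi, hr,
        resolutions["high_intensity"], resolutions["high_resolution"],
        seed=7, n_starts=8,
    )


@pytest.fixture(scope="session")
def water_pair_358(truth, q_grid, resolutions):
    data = generate_qens_dataset(
        truth,
        design=[
            ("headgroup_plus_water", "high_intensity", 358.0),
            ("headgroup_plus_water", "high_resolution", 358.0),
        ],
        q_values=q_grid,
        resolutions=resolutions,
    )
    return (
        data[("headgroup_plus_water", "high_intensity", 358.0)],
        data[("headgroup_plus_water", "high_resolution", 358.0)],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
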