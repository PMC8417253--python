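import numpy as np
import pytest

import radstab as rs


@pytest.fixture(scope="session")
def flavors():
    return {name: rs.get_flavor(name) for name in rs.SHIPPED_FLAVORS}


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic textured phantom with a full-coverage ROI."""
    rng = np.random.default_rng(1234)
    values = rng.uniform(0, 4095, size=(3, 16, 16))
    return rs.make_phantom_roi("listed", values=values, spacing=(4.0, 2.0, 2.0))


@pytest.fixture(scope="session")
def small_cohort():
    """A small but separable two-group cohort for integration tests."""
    config = rs.CohortConfig(
        n_patients=10, n_timepoints=4, grid_shape=(10, 32, 32), seed=11,
        trajectory_params={
            "A": rs.GroupTrajectory(mean=(1100, 1300, 1500, 1700),
                                    spread=(180, 190, 200, 210),
                                    radius_mm=(14, 12, 10, 8)),
            "B": rs.GroupTrajectory(mean=(1100, 1120, 1140, 1160),
                                    spread=(180, 180, 180, 180),
                                    radius_mm=(14, 13.8, 13.6, 13.4)),
        })
    return config, rs.generate_cohort(config)


def random_discrete_roi(rng, max_shape=(3, 16, 16), n_levels=8):
    """Random discretized ROI (levels 1..n_levels, 0 outside) for oracles."""
    shape = tuple(int(rng.integers(2, m + 1)) if i else int(rng.integers(1, m + 1))
                  for i, m in enumerate(max_shape))
    levels = rng.integers(1, n_levels + 1, size=shape)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[0] = True
    return np.where(mask, levels, 0).astype(np.int64)
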