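import numpy as np
import pytest

from ecostatus import IndicatorMatrix, IndicatorSet, build_series


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def two_at_target():
    """Two indicators observed exactly at their targets in both years."""
    return IndicatorSet((
        build_series("LFI", [2007, 2008], [0.485, 0.485], 0.05, target=0.485),
        build_series("ppDDE", [2007, 2008], [120.0, 120.0], 10.0,
                     direction="lower_is_better", target=120.0),
    ))


@pytest.fixture
def random_matrix(rng):
    """A 10 x 6 indicator matrix with mild correlation, for ordination oracles."""
    base = rng.standard_normal((10, 2))
    mix = rng.standard_normal((2, 6))
    values = base @ mix + 0.8 * rng.standard_normal((10, 6))
    years = tuple(range(2000, 2010))
    ids = tuple(f"V{j}" for j in range(6))
    return IndicatorMatrix(times=years, indicator_ids=ids, values=values)
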