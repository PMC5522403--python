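import numpy as np
import pytest

from topomem import stimulus


@pytest.fixture(scope="session")
def grid():
    """48-pixel grid over the +/-10 deg mapped field."""
    return stimulus.make_grid(10.0, 48)


@pytest.fixture(scope="session")
def mapping_movie(grid):
    """Three-width mapping run (1, 2, 3 deg bars, 8 directions each)."""
    parts = [stimulus.default_mapping_movie(grid, width_deg=w)
             for w in (1.0, 2.0, 3.0)]
    return stimulus.concat_movies(parts)


@pytest.fixture(scope="session")
def small_movie(grid):
    """Single-width run, used where fit accuracy is not under test."""
    return stimulus.default_mapping_movie(grid, width_deg=2.0)
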