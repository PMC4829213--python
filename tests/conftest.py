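import numpy as np
import pytest

from traffiq import scenario_registry, simulate_cohort, render_movie
from traffiq.pipeline import long_mode_optics


@pytest.fixture(scope="session")
def registry():
    return scenario_registry()


@pytest.fixture(scope="session")
def rre_rev_history(registry):
    """One short RRE_Rev cell history shared across read-only tests."""
    return simulate_cohort(
        registry["RRE_Rev"], 1, 17, t_end_h=6.0, frame_interval_h=0.5
    )[0]


@pytest.fixture(scope="session")
def rendered_cell(registry):
    """A rendered endpoint frame (all channels) of one exporting cell."""
    cfg = registry["RRE_Rev"].replace(frac_exporting=1.0, penetrance=0.0)
    h = simulate_cohort(cfg, 1, 23, t_end_h=20.0, frame_interval_h=20.0)[0]
    optics = long_mode_optics()
    movie = render_movie(h, h.geometry, optics, 31, frame_indices=np.array([1]))
    return h, movie
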