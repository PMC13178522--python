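import warnings

import numpy as np
import pytest

from fibrediff.simulate import (render_frame, simulate_timecourse_truth,
                                tetanus_config)

# noisy fits occasionally warn about degenerate decompositions; that is part
# of normal operation and would otherwise flood the test output
warnings.filterwarnings("ignore", message=".*degenerate.*")


@pytest.fixture(scope="session")
def tetanus_truth():
    """Ground truth for a standard tetanus with off-centre, tilted detector."""
    config = tetanus_config(seed=7, beam_offset=(1.7, -2.3), tilt=0.4)
    return simulate_timecourse_truth(config)


@pytest.fixture(scope="session")
def rest_frame(tetanus_truth):
    """Rendered small-angle frame of resting muscle (frame 0)."""
    return render_frame(tetanus_truth, 0, bank="sa")


@pytest.fixture(scope="session")
def active_frame(tetanus_truth):
    """Rendered small-angle frame near peak force (frame 30)."""
    return render_frame(tetanus_truth, 30, bank="sa")


@pytest.fixture(scope="session")
def rest_frame_reduced(rest_frame):
    from fibrediff.reduction import find_centre_and_tilt, mirror
    return mirror(find_centre_and_tilt(rest_frame), "both")


@pytest.fixture(scope="session")
def active_frame_reduced(active_frame):
    from fibrediff.reduction import find_centre_and_tilt, mirror
    return mirror(find_centre_and_tilt(active_frame), "both")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)
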