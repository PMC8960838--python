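import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # tests/oracles.py

from evlock import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_design():
    """Two subjects, one session, three regions, wide trial spacing."""
    return sim.TaskDesign(
        n_subjects=2,
        n_sessions=1,
        n_regions=3,
        n_trials_per_class={"POScorr": 20, "LURfalse": 20},
        iti_seconds=sim.IntervalSpec(36.0, 36.0),
        lock_to_tr=True,
        rng_seed=7,
    )


@pytest.fixture
def dip_template():
    """Canonical response with an initial dip (identifiable preceding min)."""
    return sim.ResponseTemplate("R000", "POScorr", dip_amplitude=-0.15)
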