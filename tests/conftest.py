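import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from forcefluct.preprocessing import ForceTrial
from forcefluct.synthetic import CohortConfig, TrialConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def white_series(rng):
    return rng.standard_normal(1680)


@pytest.fixture
def trial_2400():
    """A 20 s, 120 Hz stabilizing-hand trial at 12% of a 25 N MVC."""
    rng = np.random.default_rng(7)
    samples = 3.0 + 0.1 * rng.standard_normal(2400)
    return ForceTrial(
        samples=samples, rate_hz=120.0, hand="left", role="stabilizing",
        condition="bimanual_constant", participant_id="P01", timepoint=1,
        mvc_n=25.0)


@pytest.fixture
def small_cohort_cfg():
    """Reduced cohort for fast signal-level end-to-end runs."""
    return CohortConfig(
        counts={"CHI": (3, 2, 0, 0), "MCI": (3, 2, 0, 0)},
        trials_per_cell_constant=1, trials_per_cell_rd=1,
        trial=TrialConfig(duration_s=10.0, ramp_s=2.0, rate_hz=60.0),
        seed=11)


@pytest.fixture
def recovery_cohort_cfg():
    """Measure-scale cohort used for parameter-recovery simulations."""
    return CohortConfig(
        counts={"CHI": (20, 10, 0, 0), "MCI": (14, 8, 0, 0)}, seed=0)
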