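import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import larvaforce as lf
from larvaforce.pipeline import noiseless_params


@pytest.fixture(scope="session")
def noiseless_trial():
    """Deterministic trial: fixed increments/durations/delays, no noise."""
    return lf.simulate_trial(noiseless_params(), lf.CleftGeometry(baseline_force=25.0), seed=11)


@pytest.fixture(scope="session")
def noisy_trial():
    """Default stochastic trial with 0.5 mN sensor noise at 25 mN baseline."""
    return lf.simulate_trial(
        lf.LarvaParams(noise_sd=0.5), lf.CleftGeometry(baseline_force=25.0), seed=3
    )
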