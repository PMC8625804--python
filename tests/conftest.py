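import numpy as np
import pytest
from hypothesis import settings

from hrmscan import SimulationSpec, TransitionSpec, simulate_melt_curve

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("ci")


@pytest.fixture
def grid():
    """Default acquisition grid: 65–95 °C at 0.04 °C (25 readings/°C)."""
    return 65.0 + 0.04 * np.arange(751)


@pytest.fixture
def logistic_curve():
    """Factory: noise-free (by default) single-transition melt curve."""

    def make(tm=80.0, slope=1.0, noise_sd=0.0, seed=0, background=(200.0, -2.0, 0.0)):
        spec = SimulationSpec(
            transitions=(TransitionSpec(tm=tm, slope=slope),),
            background=background,
            noise_sd=noise_sd,
            seed=seed,
        )
        return simulate_melt_curve(spec)

    return make


@pytest.fixture
def multi_transition_curve():
    """Factory: noise-free multi-domain melt curve with equal weights."""

    def make(tms, slope=1.0, noise_sd=0.0, seed=0):
        n = len(tms)
        spec = SimulationSpec(
            transitions=tuple(
                TransitionSpec(tm=t, slope=slope, weight=1.0 / n) for t in tms
            ),
            noise_sd=noise_sd,
            seed=seed,
        )
        return simulate_melt_curve(spec)

    return make
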