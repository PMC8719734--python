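import numpy as np
import pytest

from delayosc.kernel import DelayKernel
from delayosc.simulate import (LuminescenceRecord, TrajectoryEnsemble,
                               simulate_observation, simulate_paths)
from delayosc.ttfl import TYPE_II


@pytest.fixture(scope="session")
def type_ii_series():
    """One 250-frame synthetic series from a developed Type-II oscillation."""
    from delayosc.phase import limit_cycle_history

    hist = limit_cycle_history(TYPE_II, dt=0.5)
    ens = simulate_paths(TYPE_II, horizon=125.0, dt=0.5, n_paths=1,
                         init=hist, seed=11)
    rec = simulate_observation(ens, TYPE_II, 0.5, seed=12)
    return rec.values[0]


@pytest.fixture(scope="session")
def single_location_record(type_ii_series):
    return LuminescenceRecord(values=type_ii_series[None, :], exposure=0.5,
                              layout=(1, 1))
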