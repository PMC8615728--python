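import numpy as np
import pytest

from meacomplex import ElectrodeLayout, SpikeTrainSet


@pytest.fixture
def small_layout():
    return ElectrodeLayout(n_electrodes=4)


@pytest.fixture
def poisson_trains():
    """Independent Poisson trains on 4 electrodes, 100 s, ~2 spikes/s."""
    rng = np.random.default_rng(42)
    trains = {}
    for eid in range(4):
        n = rng.poisson(200)
        trains[eid] = np.sort(rng.uniform(0.0, 100.0, n))
    return SpikeTrainSet(trains, 0.0, 100.0, ElectrodeLayout(4))


def poisson_train(rng, rate, duration):
    n = rng.poisson(rate * duration)
    t = np.sort(rng.uniform(0.0, duration, n))
    return t[np.concatenate(([True], np.diff(t) > 0))] if t.size else t
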