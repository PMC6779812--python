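"""Shared fixtures: small hand-built trains and a seeded random-train factory."""

from __future__ import annotations

import numpy as np
import pytest

from spikecpd import SpikeTrain, TimeGrid


@pytest.fixture
def three_spike_train() -> SpikeTrain:
    return SpikeTrain(times=np.array([10.0, 20.0, 25.0]), duration=100.0)


@pytest.fixture
def random_train_factory():
    """Factory for random trains with a 0.5 ms refractory floor on the ISIs
    (keeps every ISI well above the default 0.1 ms evaluation grid step)."""

    def make(seed: int, n_spikes: int = 200, mean_isi: float = 15.0) -> SpikeTrain:
        rng = np.random.default_rng(seed)
        isis = 0.5 + rng.exponential(mean_isi - 0.5, size=n_spikes)
        times = 1.0 + np.cumsum(isis)
        return SpikeTrain(times=times, duration=float(times[-1]) + 50.0)

    return make


@pytest.fixture
def default_grid() -> TimeGrid:
    return TimeGrid(dt=0.1, start=0.0, end=200.0)
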