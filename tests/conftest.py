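import logging

import numpy as np
import pytest

from pcimove.io import Track

logging.getLogger("pcimove").setLevel(logging.ERROR)


@pytest.fixture
def toy_track() -> Track:
    """10 still frames, 10 frames stepping 2 mm in x, 10 still; dt = 1.6 s."""
    x = np.concatenate([np.zeros(10), np.cumsum(np.full(10, 2.0)),
                        np.full(10, 20.0)])
    return Track("toy", "paper", np.arange(30) * 1.6,
                 np.column_stack([x + 100.0, np.full(30, 100.0)]))


@pytest.fixture
def brownian_cohort():
    """50 unbounded 2-D Brownian walkers sampled at 1.6 s, D = 2 mm^2/s."""
    D, dt, T = 2.0, 1.6, 5400.0
    n = int(T / dt)
    rng = np.random.default_rng(7)
    tracks, pci_ends = [], {}
    for i in range(50):
        steps = rng.normal(0.0, np.sqrt(2 * D * dt), size=(n, 2))
        xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + 112.5
        tr = Track(f"w{i}", "paper", np.arange(n + 1) * dt, xy)
        tracks.append(tr)
        pci_ends[f"w{i}"] = 0.0
    return tracks, pci_ends, D
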