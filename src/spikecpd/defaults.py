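"""Default parameter grids for sweeps and method comparison.

The window-size and ISI-weight grids mirror the sweep structure used to
characterise the methods (17 values each); the threshold grids are
logarithmically spaced over each method's plausible operating range and are
meant to be overridden when a recording's rate regime differs markedly.
"""

from __future__ import annotations

import numpy as np

#: Moving-average window sizes, ms (17 values).
WINDOW_SIZES: tuple[float, ...] = tuple(
    float(w) for w in list(range(5, 51, 5)) + list(range(60, 101, 10)) + [150, 200]
)

#: Weights of the second previous ISI (17 values, 0 .. 1).
OMEGA_GRID: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 17))

#: Number of logarithmic ISI categories for the classification method.
DEFAULT_K: int = 10

#: Classifier training windows (ms offsets after a change).  The decrease
#: window starts later than the accepted range to limit "false training" on
#: time points where the response has not yet collapsed.
TRAIN_WINDOW_INCREASE: tuple[float, float] = (10.0, 40.0)
TRAIN_WINDOW_DECREASE: tuple[float, float] = (20.0, 65.0)

#: Default evaluation grid step, ms.
DEFAULT_DT: float = 0.1

#: Default threshold grids per (method, direction).
DEFAULT_THRESHOLDS: dict[tuple[str, str], np.ndarray] = {
    ("moving_average", "increase"): np.geomspace(0.1, 30.0, 17),
    ("moving_average", "decrease"): np.geomspace(0.05, 8.0, 17),
    ("pure_isi", "increase"): np.geomspace(0.5, 40.0, 17),
    ("pure_isi", "decrease"): np.geomspace(10.0, 300.0, 17),
    ("isi_ratio", "increase"): np.geomspace(0.02, 0.95, 17),
    ("isi_ratio", "decrease"): np.geomspace(1.05, 12.0, 17),
    ("classification", "increase"): np.linspace(0.0, 0.95, 20),
    ("classification", "decrease"): np.linspace(0.0, 0.95, 20),
}


def default_thresholds(method: str, direction: str) -> np.ndarray:
    try:
        return DEFAULT_THRESHOLDS[(method, direction)].copy()
    except KeyError:
        raise KeyError(f"no default threshold grid for {method}/{direction}") from None
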