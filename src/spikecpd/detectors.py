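"""Online change-point detectors for single-neuron spike trains.

Four methods produce putative change points (CPs) for stimulus intensity
increases and decreases independently:

* **Moving-Average** — the instantaneous spike rate ``1/I_a(t)`` is compared
  against the mean +/- a multiple of the standard deviation of the rate over
  the trailing window ``[t - W, t]``.
* **Pure-ISI** — the adjusting ISI itself is thresholded: particularly short
  ISIs signal increases, particularly long ones decreases.
* **ISI-Ratio** — the ratio ``R(t, omega) = I_a(t) / I_pre(t, omega)`` is
  thresholded below 1 for increases (evaluated at spike times) and above 1
  for decreases (any time point).
* **Classification** — a naive-Bayes-style classifier over logarithmically
  binned (previous ISI, adjusting ISI) category pairs, trained per direction
  on trials with known change times and applied with leave-one-out
  cross-validation.

Continuous time is evaluated on a uniform grid (default 0.1 ms).  Threshold
crossings are turned into putative CPs by :func:`extract_cps`: only the
first grid point of a crossing episode counts, the detector re-arms after
the episode has lasted longer than the accepted-time-range length, and at
most one CP may fall between any two consecutive spikes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ConfigurationError, SpikeTrain, isi_series

__all__ = [
    "ThresholdPair",
    "TimeGrid",
    "DetectionResult",
    "ClassifierModel",
    "extract_cps",
    "MovingAverageDetector",
    "PureISIDetector",
    "ISIRatioDetector",
    "ClassificationDetector",
    "detect_moving_average",
    "detect_pure_isi",
    "detect_isi_ratio",
    "fit_classifier",
    "detect_classification",
    "loo_classification",
]

# Accepted-time-range lengths, ms; the detector re-arms after a continuous
# crossing of this length (increases [10, 40] -> 30, decreases [15, 55] -> 40).
RESET_LEN_INCREASE = 30.0
RESET_LEN_DECREASE = 40.0


@dataclass(frozen=True)
class ThresholdPair:
    """Detection thresholds for the increase and decrease channels.

    Units are method specific: SD multiples (Moving-Average), ms (Pure-ISI),
    dimensionless ratio (ISI-Ratio, ``theta_in < 1 < theta_de``) or a
    probability in [0, 1] (classification).
    """

    theta_in: float
    theta_de: float


@dataclass(frozen=True)
class TimeGrid:
    """Uniform evaluation grid for the continuous-time quantities."""

    dt: float = 0.1
    start: float = 0.0
    end: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not self.start < self.end:
            raise ConfigurationError("grid start must precede end")

    @property
    def n(self) -> int:
        return int(math.floor((self.end - self.start) / self.dt + 1e-9)) + 1

    def times(self) -> np.ndarray:
        return self.start + self.dt * np.arange(self.n)


@dataclass(frozen=True)
class DetectionResult:
    """Putative CP times of one direction for one trial."""

    direction: str
    cp_times: np.ndarray
    method: str
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cp_times", np.asarray(self.cp_times, dtype=float))

    @property
    def n_cps(self) -> int:
        return int(self.cp_times.size)


def _reset_len(direction: str) -> float:
    if direction == "increase":
        return RESET_LEN_INCREASE
    if direction == "decrease":
        return RESET_LEN_DECREASE
    raise ConfigurationError(f"unknown direction {direction!r}")


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (first, last) index pairs."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if m[0]:
        starts = np.concatenate([[0], starts])
    if m[-1]:
        ends = np.concatenate([ends, [m.size - 1]])
    return list(zip(starts.tolist(), ends.tolist()))


def _extract(
    indicator: np.ndarray,
    grid_times: np.ndarray,
    spike_times: np.ndarray,
    accept_len: float,
    dt: float,
    spike_bins: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Episode-based CP extraction (see :func:`extract_cps`).

    ``spike_bins`` restricts emitted CPs to grid bins containing a spike
    (used for channels that can only fire at spike times); a candidate is
    then deferred to the first spike bin at or after it within its episode.
    """
    if accept_len <= 0:
        raise ConfigurationError("accept_len must be positive")
    step = max(1, math.ceil(accept_len / dt - 1e-9))
    cps: list[float] = []
    last_interval = -1
    last_idx = -1
    for a, b in _runs(indicator):
        for c in range(a, b + 1, step):
            g = c
            if spike_bins is not None:
                hits = np.flatnonzero(spike_bins[c : b + 1])
                if hits.size == 0:
                    break  # no spike bin left in this episode
                g = c + int(hits[0])
            if g == last_idx:
                continue
            t = grid_times[g]
            interval = int(np.searchsorted(spike_times, t, side="right"))
            if interval != last_interval or not cps:
                cps.append(float(t))
                last_interval = interval
                last_idx = g
    return np.asarray(cps)


def extract_cps(
    indicator: np.ndarray,
    train: SpikeTrain,
    accept_len: float,
    grid: TimeGrid,
) -> np.ndarray:
    """Convert a boolean threshold-crossing series into putative CP times.

    Rules applied, in order:

    1. only the first grid time of each continuous crossing episode is a
       putative CP;
    2. if the crossing persists for longer than ``accept_len``, the detector
       is reset and may emit again (every further ``accept_len`` of
       continuous crossing);
    3. at most one putative CP may lie between any two consecutive spikes.
    """
    t = grid.times()
    ind = np.asarray(indicator, dtype=bool)
    if ind.shape != t.shape:
        raise ConfigurationError("indicator must match the grid length")
    return _extract(ind, t, train.times, accept_len, grid.dt)


# ---------------------------------------------------------------------------
# Moving-Average method


class MovingAverageDetector:
    """Instantaneous rate vs. trailing mean +/- theta * SD over ``[t-W, t]``.

    Mean and SD (population form) are computed over the grid-sampled rate in
    the trailing window; samples whose window is not fully populated with
    defined rate values are masked.  Increase CPs are restricted to spike
    times; decreases may fall between spikes.
    """

    method = "moving_average"

    def __init__(self, train: SpikeTrain, grid: TimeGrid, window: float):
        if window <= 0:
            raise ConfigurationError("window must be positive")
        self.train = train
        self.grid = grid
        self.window = float(window)
        self._t = grid.times()
        ser = isi_series(train.times, self._t, grid.dt)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = 1.0 / ser["i_a"]
        self._spike_bin = ser["spike_bin"]
        self._rate = r

        m = int(round(window / grid.dt)) + 1  # samples in [t - W, t]
        finite = np.isfinite(r)
        # center before accumulating to limit cancellation error in the
        # running sums; tiny residual variance is clipped to exactly zero
        center = float(np.mean(r[finite])) if finite.any() else 0.0
        x = np.where(finite, r - center, 0.0)
        c1 = np.concatenate([[0.0], np.cumsum(x)])
        c2 = np.concatenate([[0.0], np.cumsum(x * x)])
        cn = np.concatenate([[0], np.cumsum(finite)])
        n = r.size
        mean = np.full(n, np.nan)
        sd = np.full(n, np.nan)
        if n >= m:
            idx = np.arange(m - 1, n)
            full = (cn[idx + 1] - cn[idx + 1 - m]) == m
            s1 = c1[idx + 1] - c1[idx + 1 - m]
            s2 = c2[idx + 1] - c2[idx + 1 - m]
            mu = s1 / m
            var = np.maximum(s2 / m - mu * mu, 0.0)
            noise = 1e-12 * max(center * center, 1e-12)
            var[var < noise] = 0.0
            mean[idx[full]] = mu[full] + center
            sd[idx[full]] = np.sqrt(var[full])
        self._mean = mean
        self._sd = sd
        self._valid = finite & np.isfinite(mean)
        # absolute guard against round-off in the band comparison
        self._tol = 1e-9 * max(1.0, float(np.max(np.abs(r[finite]))) if finite.any() else 1.0)

    def indicator(self, direction: str, theta: float) -> np.ndarray:
        if theta <= 0:
            raise ConfigurationError("Moving-Average thresholds must be positive")
        with np.errstate(invalid="ignore"):
            if direction == "increase":
                e = self._rate > self._mean + theta * self._sd + self._tol
            elif direction == "decrease":
                e = self._rate < self._mean - theta * self._sd - self._tol
            else:
                raise ConfigurationError(f"unknown direction {direction!r}")
        return e & self._valid

    def detect(self, direction: str, theta: float) -> DetectionResult:
        e = self.indicator(direction, theta)
        bins = self._spike_bin if direction == "increase" else None
        cps = _extract(
            e, self._t, self.train.times, _reset_len(direction), self.grid.dt,
            spike_bins=bins,
        )
        return DetectionResult(
            direction, cps, self.method,
            {"window": self.window, "theta": theta, "dt": self.grid.dt},
        )


def detect_moving_average(
    train: SpikeTrain, grid: TimeGrid, window: float, thr: ThresholdPair
) -> tuple[DetectionResult, DetectionResult]:
    det = MovingAverageDetector(train, grid, window)
    return det.detect("increase", thr.theta_in), det.detect("decrease", thr.theta_de)


# ---------------------------------------------------------------------------
# Pure-ISI method


class PureISIDetector:
    """Thresholds on the adjusting ISI: short ISIs -> increase, long -> decrease."""

    method = "pure_isi"

    def __init__(self, train: SpikeTrain, grid: TimeGrid):
        self.train = train
        self.grid = grid
        self._t = grid.times()
        ser = isi_series(train.times, self._t, grid.dt)
        self._i_a = ser["i_a"]
        self._valid = np.isfinite(self._i_a)

    def indicator(self, direction: str, theta: float) -> np.ndarray:
        if theta <= 0:
            raise ConfigurationError("Pure-ISI thresholds must be positive (ms)")
        with np.errstate(invalid="ignore"):
            if direction == "increase":
                e = self._i_a < theta
            elif direction == "decrease":
                e = self._i_a > theta
            else:
                raise ConfigurationError(f"unknown direction {direction!r}")
        return e & self._valid

    def detect(self, direction: str, theta: float) -> DetectionResult:
        e = self.indicator(direction, theta)
        cps = _extract(
            e, self._t, self.train.times, _reset_len(direction), self.grid.dt
        )
        return DetectionResult(
            direction, cps, self.method, {"theta": theta, "dt": self.grid.dt}
        )


def detect_pure_isi(
    train: SpikeTrain, grid: TimeGrid, thr: ThresholdPair
) -> tuple[DetectionResult, DetectionResult]:
    det = PureISIDetector(train, grid)
    return det.detect("increase", thr.theta_in), det.detect("decrease", thr.theta_de)


# ---------------------------------------------------------------------------
# ISI-Ratio method


class ISIRatioDetector:
    """Threshold on ``R(t, omega) = I_a(t) / I_pre(t, omega)``.

    The increase channel is evaluated at spike times: a spike is a threshold
    crossing when its ratio falls below ``theta_in`` and the crossing state
    is held until a spike whose ratio does not cross, so that only the first
    spike of a crossing episode fires.  The decrease channel is evaluated at
    every grid point; the crossing time of the linearly growing ratio during
    a pause is ``s1 + theta_de * I_pre``.
    """

    method = "isi_ratio"

    def __init__(self, train: SpikeTrain, grid: TimeGrid, omega: float):
        if not 0.0 <= omega <= 1.0:
            raise ConfigurationError("omega must lie in [0, 1]")
        self.train = train
        self.grid = grid
        self.omega = float(omega)
        self._t = grid.times()
        ser = isi_series(train.times, self._t, grid.dt, omega=omega)
        with np.errstate(invalid="ignore", divide="ignore"):
            self._ratio = ser["i_a"] / ser["i_pre"]
        self._spike_bin = ser["spike_bin"]
        self._s1_index = ser["s1_index"]
        # per-spike ratio i1 / ((1-w)*i2 + w*i3), sample-and-held over the
        # following inter-spike interval for the increase channel
        sp = train.times
        n_sp = sp.size
        r_spk = np.full(n_sp, np.nan)
        if omega == 0.0 and n_sp >= 3:
            i1 = sp[2:] - sp[1:-1]
            i2 = sp[1:-1] - sp[:-2]
            r_spk[2:] = i1 / i2
        elif omega > 0.0 and n_sp >= 4:
            i1 = sp[3:] - sp[2:-1]
            i2 = sp[2:-1] - sp[1:-2]
            i3 = sp[1:-2] - sp[:-3]
            r_spk[3:] = i1 / ((1.0 - omega) * i2 + omega * i3)
        self._ratio_at_spike = r_spk

    def indicator(self, direction: str, theta: float) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            if direction == "increase":
                if not 0 < theta < 1:
                    raise ConfigurationError("theta_in must lie in (0, 1)")
                j = self._s1_index
                held = np.full(j.shape, np.nan)
                has = j >= 0
                held[has] = self._ratio_at_spike[j[has]]
                return np.isfinite(held) & (held < theta)
            if direction == "decrease":
                if theta <= 1:
                    raise ConfigurationError("theta_de must exceed 1")
                return np.isfinite(self._ratio) & (self._ratio > theta)
        raise ConfigurationError(f"unknown direction {direction!r}")

    def detect(self, direction: str, theta: float) -> DetectionResult:
        e = self.indicator(direction, theta)
        bins = self._spike_bin if direction == "increase" else None
        cps = _extract(
            e, self._t, self.train.times, _reset_len(direction), self.grid.dt,
            spike_bins=bins,
        )
        return DetectionResult(
            direction, cps, self.method,
            {"omega": self.omega, "theta": theta, "dt": self.grid.dt},
        )


def detect_isi_ratio(
    train: SpikeTrain, grid: TimeGrid, omega: float, thr: ThresholdPair
) -> tuple[DetectionResult, DetectionResult]:
    det = ISIRatioDetector(train, grid, omega)
    return det.detect("increase", thr.theta_in), det.detect("decrease", thr.theta_de)


# ---------------------------------------------------------------------------
# Classification method


@dataclass(frozen=True)
class ClassifierModel:
    """Category borders and relative-frequency table of ISI-pair categories.

    ``borders`` are ``e_0 = 0 < e_1 < ... < e_{k-1} < e_k = inf`` with the
    inner borders geometrically spaced between the minimum (``a``) and
    maximum (``b``) ISI of the training data, ``e_j = a * (b/a)**(j/k)``.
    ``freq[k1-1, k2-1]`` is the relative frequency with which the category
    pair ``(C_pre, C_a) = (k1, k2)`` arose inside the training window after
    a change of the target direction; unseen pairs carry frequency 0.
    """

    borders: np.ndarray
    k: int
    omega: float
    freq: np.ndarray
    counts_in: np.ndarray
    counts_cde: np.ndarray
    direction: str
    train_window: tuple[float, float]

    def categorize(self, values: np.ndarray) -> np.ndarray:
        """Category index in 1..k with ``e_{c-1} < value <= e_c`` (NaN -> 0)."""
        v = np.asarray(values, dtype=float)
        inner = self.borders[1:-1]
        c = np.searchsorted(inner, v, side="left") + 1
        c = np.where(np.isfinite(v), c, 0)
        return c.astype(int)


def category_borders(a: float, b: float, k: int) -> np.ndarray:
    """Logarithmically spaced category borders ``e_0..e_k`` for ISIs in ms."""
    if k < 2:
        raise ConfigurationError("need at least 2 categories")
    if not 0 < a < b:
        raise ConfigurationError("need 0 < min ISI < max ISI in the training data")
    j = np.arange(1, k)
    inner = a * (b / a) ** (j / k)
    return np.concatenate([[0.0], inner, [np.inf]])


def _window_mask(grid_times: np.ndarray, changes: Sequence[float], lo: float, hi: float) -> np.ndarray:
    mask = np.zeros(grid_times.size, dtype=bool)
    for c in changes:
        mask |= (grid_times >= c + lo) & (grid_times <= c + hi)
    return mask


def fit_classifier(
    trains: Sequence[SpikeTrain],
    changes: Sequence[float],
    omega: float,
    k: int,
    train_window: tuple[float, float],
    grid: TimeGrid,
    direction: str = "increase",
) -> ClassifierModel:
    """Learn the ISI-pair category statistics from training trials.

    Every valid grid point of every training trial is assigned a category
    pair ``(C_pre, C_a)``; points within ``train_window`` after a change of
    the target direction are counted into ``N_in``, all other valid points
    into ``N_c,de``, and the relative frequency is
    ``f = N_in / (N_in + N_c,de)`` (0 where both counts are zero).
    """
    if not trains:
        raise ConfigurationError("need at least one training trial")
    all_isis = np.concatenate([tr.isis() for tr in trains if tr.n_spikes >= 2])
    if all_isis.size == 0:
        raise ConfigurationError("training trials contain no ISIs")
    a, b = float(all_isis.min()), float(all_isis.max())
    borders = category_borders(a, b, k)
    lo, hi = float(train_window[0]), float(train_window[1])
    if not lo < hi:
        raise ConfigurationError("train_window must satisfy lo < hi")

    t = grid.times()
    in_mask = _window_mask(t, changes, lo, hi)
    counts_in = np.zeros((k, k), dtype=np.int64)
    counts_cde = np.zeros((k, k), dtype=np.int64)
    inner = borders[1:-1]
    for tr in trains:
        ser = isi_series(tr.times, t, grid.dt, omega=omega)
        valid = np.isfinite(ser["i_a"]) & np.isfinite(ser["i_pre"])
        c_a = np.searchsorted(inner, ser["i_a"][valid], side="left")
        c_pre = np.searchsorted(inner, ser["i_pre"][valid], side="left")
        code = c_pre * k + c_a
        w = in_mask[valid]
        counts_in += np.bincount(code[w], minlength=k * k).reshape(k, k)
        counts_cde += np.bincount(code[~w], minlength=k * k).reshape(k, k)

    total = counts_in + counts_cde
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total > 0, counts_in / np.maximum(total, 1), 0.0)
    return ClassifierModel(
        borders=borders,
        k=int(k),
        omega=float(omega),
        freq=freq,
        counts_in=counts_in,
        counts_cde=counts_cde,
        direction=direction,
        train_window=(lo, hi),
    )


class ClassificationDetector:
    """Apply a fitted :class:`ClassifierModel` to a test trial.

    The change probability ``P(t)`` is the learned relative frequency of the
    trial's category pair at ``t``; crossings of ``P(t) > theta`` are turned
    into putative CPs with the usual episode rules.
    """

    method = "classification"

    def __init__(self, model: ClassifierModel, train: SpikeTrain, grid: TimeGrid):
        self.model = model
        self.train = train
        self.grid = grid
        self._t = grid.times()
        ser = isi_series(train.times, self._t, grid.dt, omega=model.omega)
        valid = np.isfinite(ser["i_a"]) & np.isfinite(ser["i_pre"])
        p = np.full(self._t.size, np.nan)
        inner = model.borders[1:-1]
        c_a = np.searchsorted(inner, ser["i_a"][valid], side="left")
        c_pre = np.searchsorted(inner, ser["i_pre"][valid], side="left")
        p[valid] = model.freq[c_pre, c_a]
        self._p = p
        self._valid = valid

    @property
    def probability(self) -> np.ndarray:
        return self._p

    def indicator(self, direction: str, theta: float) -> np.ndarray:
        if not 0.0 <= theta <= 1.0:
            raise ConfigurationError("classification threshold must lie in [0, 1]")
        with np.errstate(invalid="ignore"):
            return self._valid & (self._p > theta)

    def detect(self, direction: Optional[str] = None, theta: float = 0.5) -> DetectionResult:
        direction = direction or self.model.direction
        e = self.indicator(direction, theta)
        cps = _extract(
            e, self._t, self.train.times, _reset_len(direction), self.grid.dt
        )
        return DetectionResult(
            direction, cps, self.method,
            {"omega": self.model.omega, "k": self.model.k, "theta": theta,
             "dt": self.grid.dt},
        )


def detect_classification(
    model: ClassifierModel, train: SpikeTrain, grid: TimeGrid, theta: float
) -> DetectionResult:
    return ClassificationDetector(model, train, grid).detect(model.direction, theta)


def loo_classification(
    trains: Sequence[SpikeTrain],
    changes: Sequence[float],
    omega: float,
    k: int,
    train_window: tuple[float, float],
    theta: float,
    grid: TimeGrid,
    direction: str = "increase",
) -> list[DetectionResult]:
    """Leave-one-out cross-validation: fit on ``m - 1`` trials, detect on the
    held-out trial; returns one result per trial, in trial order."""
    if len(trains) < 2:
        raise ConfigurationError("leave-one-out needs at least 2 trials")
    results = []
    for i, test in enumerate(trains):
        fold = [tr for j, tr in enumerate(trains) if j != i]
        model = fit_classifier(fold, changes, omega, k, train_window, grid, direction)
        results.append(detect_classification(model, test, grid, theta))
    return results
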