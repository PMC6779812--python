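"""Spike-time indexing and interspike-interval (ISI) quantities.

All detectors in this package are built from three online quantities
evaluated at an arbitrary query time ``t`` (milliseconds):

* the *adjusting ISI* ``I_a(t)``: the last completed ISI, replaced by the
  elapsed time since the last spike once that elapsed time exceeds it.  It
  is causal (uses no future spikes) and grows linearly during pauses.
* the *weighted previous ISI* ``I_pre(t, omega)``: a convex combination of
  the two ISIs preceding the one measured by ``I_a``, with weight ``omega``
  on the older one.  Exactly at a spike time the combination shifts back by
  one ISI so that it never includes the ISI that just ended at ``t``.
* the *instantaneous spike rate* ``1 / I_a(t)``.

Scalar functions operate on a single query time and raise
:class:`InsufficientHistoryError` during the warm-up period where a
quantity is undefined.  The ``*_series`` helpers evaluate the same
quantities on a uniform time grid (vectorised, NaN during warm-up) and are
what the detectors consume.  Grid points whose sampling bin ``(t - dt, t]``
contains a spike are evaluated *at that spike time*, so the at-spike branch
of ``I_pre`` is honoured even when spikes fall between grid points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "InsufficientHistoryError",
    "ConfigurationError",
    "SpikeTrain",
    "ISIContext",
    "isi_context",
    "adjusting_isi",
    "weighted_previous_isi",
    "instantaneous_rate",
    "isi_series",
]


class InsufficientHistoryError(ValueError):
    """Raised when a query time precedes the spikes required by a quantity."""


class ConfigurationError(ValueError):
    """Raised for invalid parameter combinations or malformed inputs."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one trial, in milliseconds.

    Parameters
    ----------
    times
        Strictly increasing spike times in ``[0, duration]``.
    duration
        Recording length ``D`` in ms; must be positive.
    trial_id
        Integer label of the trial within a recording.
    """

    times: np.ndarray
    duration: float
    trial_id: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ConfigurationError("spike times must be one-dimensional")
        if self.duration <= 0:
            raise ConfigurationError("duration must be positive")
        if t.size:
            if np.any(np.diff(t) <= 0):
                raise ConfigurationError("spike times must be strictly increasing")
            if t[0] < 0 or t[-1] > self.duration:
                raise ConfigurationError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        """Completed ISIs of the trial (``diff`` of the spike times)."""
        return np.diff(self.times)


@dataclass(frozen=True)
class ISIContext:
    """Previous spike times and ISIs at a query time.

    ``s1`` is the last spike at or before ``t`` (inclusive: a query exactly
    at a spike resolves to that spike), ``s2``..``s4`` the earlier spikes,
    ``i1 = s1 - s2`` etc.  Fields beyond the requested order are ``None``.
    """

    t: float
    s1: float
    s2: float
    s3: Optional[float] = None
    s4: Optional[float] = None
    i1: float = field(default=np.nan)
    i2: Optional[float] = None
    i3: Optional[float] = None


def _s1_index(times: np.ndarray, t: float) -> int:
    """Index of the last spike at or before ``t`` (or -1)."""
    return int(np.searchsorted(times, t, side="right")) - 1


def isi_context(train: SpikeTrain, t: float, max_order: int = 2) -> ISIContext:
    """Previous spikes of order 1..``max_order`` and their ISIs at time ``t``.

    Raises
    ------
    InsufficientHistoryError
        If fewer than ``max_order`` spikes occur at or before ``t``.
    """
    if max_order not in (2, 3, 4):
        raise ConfigurationError("max_order must be 2, 3 or 4")
    j = _s1_index(train.times, t)
    if j + 1 < max_order:
        raise InsufficientHistoryError(
            f"need {max_order} spikes at or before t={t}, have {j + 1}"
        )
    s = [float(train.times[j - i]) for i in range(max_order)]
    i_vals = [s[i] - s[i + 1] for i in range(max_order - 1)]
    return ISIContext(
        t=t,
        s1=s[0],
        s2=s[1],
        s3=s[2] if max_order >= 3 else None,
        s4=s[3] if max_order >= 4 else None,
        i1=i_vals[0],
        i2=i_vals[1] if max_order >= 3 else None,
        i3=i_vals[2] if max_order >= 4 else None,
    )


def adjusting_isi(train: SpikeTrain, t: float) -> float:
    """Adjusting ISI ``I_a(t)``: the last ISI, or the elapsed time since the
    last spike once that exceeds it.

    Requires at least two spikes at or before ``t``.
    """
    ctx = isi_context(train, t, max_order=2)
    elapsed = t - ctx.s1
    return ctx.i1 if elapsed < ctx.i1 else elapsed


def weighted_previous_isi(train: SpikeTrain, t: float, omega: float) -> float:
    """Weighted previous ISI ``I_pre(t, omega)``.

    For ``t`` strictly between spikes this is ``(1-omega)*i1 + omega*i2``;
    exactly at a spike time the combination shifts one ISI back,
    ``(1-omega)*i2 + omega*i3``, so the ISI ending at ``t`` is excluded.
    Only the ISIs with non-zero weight are required to exist.
    """
    if not 0.0 <= omega <= 1.0:
        raise ConfigurationError("omega must lie in [0, 1]")
    j = _s1_index(train.times, t)
    if j < 0:
        raise InsufficientHistoryError(f"no spike at or before t={t}")
    at_spike = train.times[j] == t
    # ISI orders carrying non-zero weight for the active branch
    lo = 2 if at_spike else 1
    orders = []
    if omega < 1.0:
        orders.append(lo)
    if omega > 0.0:
        orders.append(lo + 1)
    need = max(orders) + 1  # s_(k+1) must exist to form i_k
    if j + 1 < need:
        raise InsufficientHistoryError(
            f"need {need} spikes at or before t={t}, have {j + 1}"
        )

    def isi(order: int) -> float:
        return float(train.times[j - order + 1] - train.times[j - order])

    first = isi(lo) if omega < 1.0 else 0.0
    second = isi(lo + 1) if omega > 0.0 else 0.0
    return (1.0 - omega) * first + omega * second


def instantaneous_rate(train: SpikeTrain, t: float) -> float:
    """Instantaneous spike rate ``1 / I_a(t)`` in 1/ms."""
    return 1.0 / adjusting_isi(train, t)


def isi_series(
    times: Sequence[float] | np.ndarray,
    grid_times: np.ndarray,
    dt: float,
    omega: Optional[float] = None,
) -> dict:
    """Evaluate ISI quantities on a uniform time grid.

    Parameters
    ----------
    times
        Sorted spike times of one trial (ms).
    grid_times
        Uniform grid of query times (ms), spacing ``dt``.
    dt
        Grid step; a grid point whose bin ``(t - dt, t]`` contains a spike
        is evaluated at that spike time (at-spike branch of ``I_pre``).
    omega
        Weight of the second previous ISI; if ``None``, ``i_pre`` is not
        computed.

    Returns
    -------
    dict with keys
        ``s1`` last spike time at or before each grid point (NaN if none);
        ``i_a`` adjusting ISI (NaN during warm-up);
        ``spike_bin`` boolean, bin contains a spike;
        ``i_pre`` weighted previous ISI (if requested; NaN during warm-up).
    """
    sp = np.asarray(times, dtype=float)
    t = np.asarray(grid_times, dtype=float)
    n = t.size
    j = np.searchsorted(sp, t, side="right") - 1

    s1 = np.full(n, np.nan)
    i1 = np.full(n, np.nan)
    i2 = np.full(n, np.nan)
    i3 = np.full(n, np.nan)
    has = j >= 0
    s1[has] = sp[j[has]]
    m = j >= 1
    i1[m] = sp[j[m]] - sp[j[m] - 1]
    m = j >= 2
    i2[m] = sp[j[m] - 1] - sp[j[m] - 2]
    m = j >= 3
    i3[m] = sp[j[m] - 2] - sp[j[m] - 3]

    spike_bin = has & (t - s1 < dt)

    with np.errstate(invalid="ignore"):
        i_a = np.where(spike_bin, i1, np.maximum(i1, t - s1))
    out = {"s1": s1, "i_a": i_a, "spike_bin": spike_bin, "s1_index": j}

    if omega is not None:
        if not 0.0 <= omega <= 1.0:
            raise ConfigurationError("omega must lie in [0, 1]")
        w = float(omega)
        with np.errstate(invalid="ignore"):
            between = (1.0 - w) * i1 + (w * i2 if w > 0 else 0.0)
            at_spike = (1.0 - w) * i2 + (w * i3 if w > 0 else 0.0)
        if w == 0.0:
            between = i1.copy()
            at_spike = i2.copy()
        i_pre = np.where(spike_bin, at_spike, between)
        out["i_pre"] = i_pre
    return out
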