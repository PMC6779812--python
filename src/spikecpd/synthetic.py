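"""Synthetic stimulus protocols and AN2-like spike-train responses.

The generator emulates the acoustic step protocols used to probe the
cricket's ultrasound-sensitive interneuron AN2 and the phenomenology of its
responses, so that the full detection/evaluation pipeline can be exercised
without recorded data:

* **Protocols** — a baseline intensity with rectangular steps every 400 ms:
  positive steps last 50 ms and are 2-18 dB above baseline (an IFB increase
  followed by a DBB decrease), negative steps last 100 ms and are 2-5 dB
  below (a DFB decrease followed by an IBB increase).  Stimulation runs from
  0.5 to 3.75 s of a 4.25 s recording; a recording has 10 trials.
* **Responses** — a piecewise firing-rate profile: each intensity increase
  triggers, after a response latency, a burst transient that adapts
  exponentially to a sustained level scaled with the step amplitude; each
  decrease triggers a transient suppression (pause) that recovers to the new
  sustained level.  Spikes are drawn from this profile by time-rescaling a
  gamma renewal process (shape 1 = inhomogeneous Poisson; larger shapes give
  more regular trains).

The model is deliberately phenomenological: it reproduces bursts (ISIs of a
few ms after increases), pauses after decreases, and spike-frequency
adaptation, not AN2 biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import ConfigurationError, SpikeTrain
from .detectors import TimeGrid

__all__ = [
    "StimulusEvent",
    "StimulusProtocol",
    "ResponseModel",
    "PRESETS",
    "make_protocol",
    "rate_profile",
    "simulate_train",
    "make_dataset",
    "min_isi_after",
]

INCREASE_TYPES = ("onset", "IFB", "IBB")
DECREASE_TYPES = ("offset", "DFB", "DBB")

POSITIVE_STEP_LEN = 50.0  # ms, duration of a positive step (IFB -> DBB)
NEGATIVE_STEP_LEN = 100.0  # ms, duration of a negative step (DFB -> IBB)
STEP_SPACING = 400.0  # ms between successive step onsets
MIN_EVENT_GAP = 300.0  # ms of baseline guaranteed around steps


@dataclass(frozen=True)
class StimulusEvent:
    """One labeled intensity change."""

    time: float
    type: str  # onset | IFB | IBB | offset | DFB | DBB
    direction: str  # increase | decrease
    amplitude: float  # dB relative to baseline after the event (0 = baseline)


@dataclass(frozen=True)
class StimulusProtocol:
    """Labeled intensity-change events of one stimulus pattern."""

    base_db: float
    events: tuple[StimulusEvent, ...]
    duration: float
    n_trials: int = 10

    def changes(self, direction: str) -> np.ndarray:
        """Sorted change times (ms) of one direction."""
        return np.asarray(
            [e.time for e in self.events if e.direction == direction], dtype=float
        )

    @property
    def stim_onset(self) -> float:
        return min(e.time for e in self.events if e.type == "onset")

    @property
    def stim_offset(self) -> float:
        return max(e.time for e in self.events if e.type == "offset")


@dataclass(frozen=True)
class ResponseModel:
    """Phenomenological AN2 response parameters.

    Parameters
    ----------
    baseline_rate
        Sustained rate (spikes/s) at the baseline intensity; also the
        spontaneous rate outside stimulation.
    gain_db
        Multiplicative rate gain per dB of intensity step; the sustained
        rate during a step of ``A`` dB is ``baseline_rate * gain_db**A``.
    onset_burst_rate
        Peak transient rate (spikes/s) right after an intensity increase;
        values at or below the sustained level produce no onset burst.
    adapt_tau
        Exponential adaptation time constant of onset transients, ms.
    suppress_tau
        Decay constant of the previous activity after an intensity
        decrease, ms: the response winds down continuously, so a strong
        response leaves a tail of short ISIs in the early accepted range
        and the pause develops late; suppression of weak activity is
        near-immediate.
    recovery_tau
        Time constant of the recovery from the suppression trough, ms;
        recovery from a pause is much slower than onset adaptation, so
        pauses typically outlast the accepted time range.
    latency
        Response delay between a stimulus change and its effect, ms.
    gamma_shape
        Shape of the gamma renewal process in rescaled time (>= 1); the ISI
        coefficient of variation at constant rate is ``1/sqrt(shape)``.
    seed
        Default RNG seed used by :func:`make_dataset`.
    """

    baseline_rate: float = 55.0
    gain_db: float = 1.08
    onset_burst_rate: float = 400.0
    adapt_tau: float = 20.0
    suppress_tau: float = 10.0
    recovery_tau: float = 150.0
    latency: float = 15.0
    gamma_shape: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.baseline_rate, self.onset_burst_rate) < 0:
            raise ConfigurationError("rates must be non-negative")
        if min(self.adapt_tau, self.suppress_tau, self.recovery_tau) <= 0:
            raise ConfigurationError("time constants must be positive")
        if self.gamma_shape < 1:
            raise ConfigurationError("gamma_shape must be >= 1")
        if self.latency < 0:
            raise ConfigurationError("latency must be non-negative")


#: Response presets spanning the observed range of response strengths:
#: "strong" — bursts with ISIs of a few ms after every increase and clear
#: pauses after decreases; "medium" — shortest post-increase ISIs in the
#: 7-40 ms range; "weak" — no onset transient at all (rate steps only);
#: "adapting" — strong bursts with slower adaptation and noisier trains, so
#: that ISIs lengthen markedly through a response before a decrease.
PRESETS: dict[str, ResponseModel] = {
    "strong": ResponseModel(),
    "medium": ResponseModel(onset_burst_rate=100.0, gain_db=1.05),
    "weak": ResponseModel(onset_burst_rate=0.0, gain_db=1.02),
    "adapting": ResponseModel(adapt_tau=30.0),
}


def make_protocol(
    base_db: float = 90.0,
    step_amplitudes_db: Optional[Sequence[float]] = None,
    n_steps: int = 6,
    duration: float = 4250.0,
    stim_onset: float = 500.0,
    stim_offset: float = 3750.0,
    seed: Optional[int] = None,
    p_positive: float = 0.7,
    n_trials: int = 10,
    step_times: Optional[Sequence[float]] = None,
) -> StimulusProtocol:
    """Build a labeled step protocol.

    ``step_amplitudes_db`` gives signed step amplitudes explicitly (positive
    entries become 50 ms positive steps, negative entries 100 ms negative
    steps); otherwise ``n_steps`` signs are drawn with probability
    ``p_positive`` of being positive and amplitudes uniform in 2-18 dB
    (positive) or 2-5 dB (negative).  Steps start 400 ms after stimulation
    onset and repeat every 400 ms unless ``step_times`` places them
    explicitly.
    """
    rng = np.random.default_rng(seed)
    if step_amplitudes_db is not None:
        amps = [float(a) for a in step_amplitudes_db]
    else:
        amps = []
        for _ in range(int(n_steps)):
            if rng.random() < p_positive:
                amps.append(float(rng.uniform(2.0, 18.0)))
            else:
                amps.append(-float(rng.uniform(2.0, 5.0)))
    if any(a == 0 for a in amps):
        raise ConfigurationError("step amplitudes must be non-zero")
    if not 0 < stim_onset < stim_offset < duration:
        raise ConfigurationError("need 0 < stim_onset < stim_offset < duration")

    if step_times is None:
        step_times = [stim_onset + STEP_SPACING * (i + 1) for i in range(len(amps))]
    else:
        step_times = sorted(float(t) for t in step_times)
        if len(step_times) != len(amps):
            raise ConfigurationError("step_times and amplitudes must match in length")
        if step_times and (
            step_times[0] < stim_onset + MIN_EVENT_GAP
            or np.any(np.diff(step_times) < STEP_SPACING)
        ):
            raise ConfigurationError("explicit step times are too closely spaced")
    if step_times and step_times[-1] + NEGATIVE_STEP_LEN + MIN_EVENT_GAP > stim_offset:
        raise ConfigurationError(
            "protocol overcrowded: steps do not fit between onset and offset"
        )

    events = [StimulusEvent(stim_onset, "onset", "increase", 0.0)]
    for t0, a in zip(step_times, amps):
        if a > 0:
            events.append(StimulusEvent(t0, "IFB", "increase", a))
            events.append(StimulusEvent(t0 + POSITIVE_STEP_LEN, "DBB", "decrease", 0.0))
        else:
            events.append(StimulusEvent(t0, "DFB", "decrease", a))
            events.append(StimulusEvent(t0 + NEGATIVE_STEP_LEN, "IBB", "increase", 0.0))
    events.append(StimulusEvent(stim_offset, "offset", "decrease", 0.0))
    events.sort(key=lambda e: e.time)
    return StimulusProtocol(
        base_db=float(base_db),
        events=tuple(events),
        duration=float(duration),
        n_trials=int(n_trials),
    )


def rate_profile(
    protocol: StimulusProtocol, model: ResponseModel, grid: TimeGrid
) -> np.ndarray:
    """Piecewise firing-rate profile (spikes/s) on the grid.

    Outside stimulation the rate is exactly ``baseline_rate``.  Each event
    acts after the response latency.  Intensity increases jump to the
    onset-burst rate (if above the new sustained target) and adapt
    exponentially (``adapt_tau``) to the target, which scales with the step
    amplitude.  Intensity decreases are continuous: the previous activity
    decays with ``suppress_tau`` (a burst tail), undershoots into a pause
    whose depth is set by the transient gain
    ``1 - baseline_rate / onset_burst_rate``, and recovers slowly
    (``recovery_tau``); a model without onset bursts therefore produces no
    pauses either.  Transients are truncated to the target exactly after 5
    time constants.
    """
    t = grid.times()
    rate = np.full(t.size, model.baseline_rate, dtype=float)

    def sustained(rel_db: Optional[float]) -> float:
        if rel_db is None:  # no stimulation
            return model.baseline_rate
        return model.baseline_rate * model.gain_db ** rel_db

    if model.onset_burst_rate > model.baseline_rate > 0:
        supp = 1.0 - model.baseline_rate / model.onset_burst_rate
    else:
        supp = 0.0

    events = [
        (ev.time + model.latency, ev.direction,
         sustained(None if ev.type == "offset" else ev.amplitude))
        for ev in protocol.events
    ]

    tf, tr = model.suppress_tau, model.recovery_tau
    if tf == tr:
        tf *= 0.999  # keep the alpha-shaped pause well defined
    t_peak = np.log(tr / tf) * tf * tr / (tr - tf)
    bump_norm = 1.0 / (np.exp(-t_peak / tr) - np.exp(-t_peak / tf))

    def segment(direction, prev_rate, target, dt_rel):
        if direction == "increase":
            r0 = max(model.onset_burst_rate, target)
            seg = target + (r0 - target) * np.exp(-dt_rel / model.adapt_tau)
            return np.where(dt_rel >= 5.0 * model.adapt_tau, target, seg)
        bump = (np.exp(-dt_rel / tr) - np.exp(-dt_rel / tf)) * bump_norm
        seg = (target + (prev_rate - target) * np.exp(-dt_rel / tf)
               - supp * target * bump)
        return np.where(dt_rel >= 5.0 * tr, target, seg)

    prev_rate = model.baseline_rate
    for i, (t0, direction, target) in enumerate(events):
        t1 = events[i + 1][0] if i + 1 < len(events) else np.inf
        sel = (t >= t0) & (t < t1)
        if sel.any():
            rate[sel] = segment(direction, prev_rate, target, t[sel] - t0)
        if np.isfinite(t1):
            prev_rate = max(
                float(segment(direction, prev_rate, target, np.asarray(t1 - t0))),
                0.0,
            )
    return np.maximum(rate, 0.0)


def simulate_train(
    rate: np.ndarray,
    times: np.ndarray,
    gamma_shape: float,
    seed,
    duration: Optional[float] = None,
    trial_id: int = 0,
) -> SpikeTrain:
    """Draw one spike train from a rate profile by time-rescaling.

    The cumulative intensity ``Lambda(t)`` (rate in spikes/s, time in ms) is
    integrated with the trapezoidal rule; unit-mean gamma increments with
    shape ``gamma_shape`` are accumulated in rescaled time and mapped back
    through ``Lambda`` by linear interpolation.  Shape 1 reduces to an
    inhomogeneous Poisson process.
    """
    r = np.asarray(rate, dtype=float)
    t = np.asarray(times, dtype=float)
    if np.any(r < 0):
        raise ConfigurationError("rate must be non-negative")
    if gamma_shape < 1:
        raise ConfigurationError("gamma_shape must be >= 1")
    if duration is None:
        duration = float(t[-1])
    rng = np.random.default_rng(seed)
    dt = np.diff(t)
    lam = np.concatenate([[0.0], np.cumsum(0.5 * (r[1:] + r[:-1]) * dt) / 1000.0])
    total = lam[-1]
    if total <= 0:
        return SpikeTrain(times=np.empty(0), duration=duration, trial_id=trial_id)
    n_draw = int(total + 4.0 * np.sqrt(total) + 25)
    targets = np.cumsum(rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_draw))
    while targets[-1] < total:  # extremely unlikely; top up deterministically
        extra = np.cumsum(rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_draw))
        targets = np.concatenate([targets, targets[-1] + extra])
    targets = targets[targets <= total]
    spikes = np.interp(targets, lam, t)
    spikes = spikes[(spikes >= 0) & (spikes <= duration)]
    keep = np.concatenate([[True], np.diff(spikes) > 0])
    return SpikeTrain(times=spikes[keep], duration=duration, trial_id=trial_id)


def make_dataset(
    protocol: StimulusProtocol,
    model: ResponseModel,
    n_trials: Optional[int] = None,
    seed: Optional[int] = None,
    dt: float = 0.5,
) -> tuple[list[SpikeTrain], dict[str, np.ndarray]]:
    """Simulate independent trials of one protocol.

    Returns the trials and the change times split by direction (the inputs
    the evaluation stage needs).  Each trial uses an independent child seed
    spawned from ``seed`` (default ``model.seed``).  ``dt`` is the rate
    integration step, ms.
    """
    if n_trials is None:
        n_trials = protocol.n_trials
    if n_trials < 1:
        raise ConfigurationError("need at least one trial")
    grid = TimeGrid(dt=dt, start=0.0, end=protocol.duration)
    rate = rate_profile(protocol, model, grid)
    t = grid.times()
    entropy = model.seed if seed is None else seed
    root = entropy if isinstance(entropy, np.random.SeedSequence) \
        else np.random.SeedSequence(entropy)
    trains = [
        simulate_train(rate, t, model.gamma_shape, child,
                       duration=protocol.duration, trial_id=i)
        for i, child in enumerate(root.spawn(n_trials))
    ]
    changes = {
        "increase": protocol.changes("increase"),
        "decrease": protocol.changes("decrease"),
    }
    return trains, changes


def min_isi_after(
    train: SpikeTrain, change: float, window: tuple[float, float] = (0.0, 40.0)
) -> float:
    """Smallest completed ISI whose spikes both fall in the post-change
    window ``[change + lo, change + hi]`` (inf if fewer than two spikes)."""
    lo, hi = window
    sel = (train.times >= change + lo) & (train.times <= change + hi)
    pts = train.times[sel]
    if pts.size < 2:
        return float("inf")
    return float(np.diff(pts).min())
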