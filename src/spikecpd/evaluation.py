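"""Continuous-time TP/FP labeling and normalized ROC/AUC evaluation.

A putative CP is a true positive when it is the *first* putative CP inside
the accepted time range ``[change + lo, change + hi]`` after a true change
of its direction; every other putative CP (later ones inside a window, and
all CPs outside every window) is a false positive.

Because the recordings are continuous, the FP count is normalized by the
maximum number of CPs that could theoretically occur: the recording
duration divided by the accepted-range length, minus the number of true
changes,

    TP-rate = #TP / n,      FP-rate = #FP / (D / |T_accept| - n).

The FP-rate can exceed 1 in principle.  ROC curves are built by sweeping a
detector threshold, computing per-trial rates and averaging them across
trials point-wise; the AUC prepends (0, 0), extends the curve horizontally
from its largest FP-rate to 1, clips FP-rates above 1, and integrates with
the trapezoidal rule over [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import ConfigurationError, SpikeTrain
from .detectors import DetectionResult

__all__ = [
    "AcceptWindow",
    "LabeledCPs",
    "ROCCurve",
    "ACCEPT_INCREASE",
    "ACCEPT_DECREASE",
    "label_cps",
    "rates",
    "roc_sweep",
    "auc",
]


@dataclass(frozen=True)
class AcceptWindow:
    """Accepted time range as offsets (ms) after a change: ``[lo, hi]``."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ConfigurationError("accept window needs 0 <= lo < hi")

    @property
    def length(self) -> float:
        return self.hi - self.lo


# Latency windows in which a response to a change is expected (ms offsets).
ACCEPT_INCREASE = AcceptWindow(10.0, 40.0)
ACCEPT_DECREASE = AcceptWindow(15.0, 55.0)


@dataclass(frozen=True)
class LabeledCPs:
    """Putative CPs split into true and false positives."""

    tp_times: np.ndarray
    fp_times: np.ndarray
    n_changes: int
    duration: float

    @property
    def n_tp(self) -> int:
        return int(self.tp_times.size)

    @property
    def n_fp(self) -> int:
        return int(self.fp_times.size)


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-swept ROC points (FP-rate, TP-rate) and their AUC."""

    points: np.ndarray  # shape (n_thresholds, 2), columns (fp_rate, tp_rate)
    auc: float
    thresholds: np.ndarray
    per_trial: np.ndarray  # shape (n_thresholds, n_trials, 2), (tp, fp) rates


def label_cps(
    cps: DetectionResult | Sequence[float] | np.ndarray,
    changes: Sequence[float],
    win: AcceptWindow,
    duration: float,
) -> LabeledCPs:
    """First-hit TP labeling of putative CPs against true change times.

    Raises :class:`ConfigurationError` if two accept windows overlap (the
    stimulus protocols guarantee well-separated same-direction changes).
    """
    times = cps.cp_times if isinstance(cps, DetectionResult) else np.asarray(cps, float)
    times = np.sort(np.asarray(times, dtype=float))
    chg = np.sort(np.asarray(changes, dtype=float))
    if chg.size >= 2 and np.any(chg[1:] + win.lo <= chg[:-1] + win.hi):
        raise ConfigurationError("accept windows overlap; check the protocol")

    tp: list[float] = []
    fp_mask = np.ones(times.size, dtype=bool)
    for c in chg:
        inside = np.flatnonzero((times >= c + win.lo) & (times <= c + win.hi))
        if inside.size:
            tp.append(float(times[inside[0]]))
            fp_mask[inside[0]] = False
    return LabeledCPs(
        tp_times=np.asarray(tp),
        fp_times=times[fp_mask],
        n_changes=int(chg.size),
        duration=float(duration),
    )


def rates(labeled: LabeledCPs, win: AcceptWindow) -> tuple[float, float]:
    """Normalized (TP-rate, FP-rate) of a labeled trial."""
    n = labeled.n_changes
    if n < 1:
        raise ConfigurationError("need at least one true change")
    denom = labeled.duration / win.length - n
    if denom <= 0:
        raise ConfigurationError("non-positive FP normalization denominator")
    return labeled.n_tp / n, labeled.n_fp / denom


def roc_sweep(
    detector_factory: Callable[[SpikeTrain], object],
    trains: Sequence[SpikeTrain],
    changes: Sequence[float],
    win: AcceptWindow,
    thresholds: Sequence[float],
    direction: str,
) -> ROCCurve:
    """Sweep a detector threshold and average per-trial rates.

    ``detector_factory(train)`` must return an object with a
    ``detect(direction, theta) -> DetectionResult`` method (all built-in
    detector classes qualify); the per-trial (TP, FP) rates at each
    threshold are averaged arithmetically across trials.
    """
    thresholds = np.asarray(list(thresholds), dtype=float)
    if thresholds.size == 0:
        raise ConfigurationError("threshold grid must be nonempty")
    per_trial = np.zeros((thresholds.size, len(trains), 2))
    for i, tr in enumerate(trains):
        det = detector_factory(tr)
        for j, th in enumerate(thresholds):
            res = det.detect(direction, float(th))
            lab = label_cps(res, changes, win, tr.duration)
            per_trial[j, i] = rates(lab, win)
    mean_tp = per_trial[:, :, 0].mean(axis=1)
    mean_fp = per_trial[:, :, 1].mean(axis=1)
    points = np.column_stack([mean_fp, mean_tp])
    return ROCCurve(points=points, auc=auc(points), thresholds=thresholds,
                    per_trial=per_trial)


def auc(curve: ROCCurve | np.ndarray) -> float:
    """Area under the ROC curve over FP-rate in [0, 1].

    Points are sorted by FP-rate, (0, 0) is prepended, the curve is extended
    horizontally from its largest FP-rate to 1, and FP-rates above 1 are
    clipped to 1 before trapezoidal integration.
    """
    pts = curve.points if isinstance(curve, ROCCurve) else np.asarray(curve, float)
    pts = np.atleast_2d(pts)
    if pts.shape[0] < 1:
        raise ConfigurationError("need at least one ROC point")
    fp = np.clip(pts[:, 0], 0.0, 1.0)
    tp = pts[:, 1]
    order = np.argsort(fp, kind="stable")
    fp, tp = fp[order], tp[order]
    fp = np.concatenate([[0.0], fp])
    tp = np.concatenate([[0.0], tp])
    if fp[-1] < 1.0:
        fp = np.concatenate([fp, [1.0]])
        tp = np.concatenate([tp, [tp[-1]]])
    return float(np.trapezoid(tp, fp))
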