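"""End-to-end evaluation pipelines: simulate -> detect -> sweep -> AUC.

These helpers tie the synthetic generator, the four detectors and the ROC
machinery together and are what both the command-line interface and the
reproduction script build on.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from . import defaults
from .core import SpikeTrain
from .detectors import (
    ClassificationDetector,
    DetectionResult,
    ISIRatioDetector,
    MovingAverageDetector,
    PureISIDetector,
    TimeGrid,
    fit_classifier,
)
from .evaluation import (
    ACCEPT_DECREASE,
    ACCEPT_INCREASE,
    AcceptWindow,
    ROCCurve,
    auc,
    label_cps,
    rates,
    roc_sweep,
)
from .synthetic import PRESETS, make_dataset, make_protocol

__all__ = [
    "METHODS",
    "accept_window",
    "standard_dataset",
    "method_roc",
    "compare_methods",
    "chance_level_auc",
    "oracle_detector_auc",
    "isi_ratio_omega_effect",
]

METHODS = ("moving_average", "pure_isi", "isi_ratio", "classification")


def accept_window(direction: str) -> AcceptWindow:
    return ACCEPT_INCREASE if direction == "increase" else ACCEPT_DECREASE


def standard_dataset(
    seed: int,
    preset: str = "strong",
    n_trials: int = 10,
    n_steps: int = 6,
    p_positive: float = 0.7,
):
    """Simulate one recording of the standard step protocol.

    Returns ``(trains, changes, protocol, model)``.  Protocol randomness
    (step signs and amplitudes) and spiking noise use independent child
    seeds spawned from ``seed``.
    """
    model = PRESETS[preset]
    s_prot, s_data = np.random.SeedSequence(seed).spawn(2)
    protocol = make_protocol(
        n_steps=n_steps, p_positive=p_positive, seed=s_prot, n_trials=n_trials
    )
    trains, changes = make_dataset(protocol, model, n_trials=n_trials, seed=s_data)
    return trains, changes, protocol, model


def _detector_factory(method: str, grid: TimeGrid, window: float, omega: float):
    if method == "moving_average":
        return lambda tr: MovingAverageDetector(tr, grid, window)
    if method == "pure_isi":
        return lambda tr: PureISIDetector(tr, grid)
    if method == "isi_ratio":
        return lambda tr: ISIRatioDetector(tr, grid, omega)
    raise KeyError(f"unknown method {method!r}")


def method_roc(
    method: str,
    trains: Sequence[SpikeTrain],
    changes: dict[str, np.ndarray],
    direction: str,
    grid: TimeGrid,
    thresholds: Optional[Sequence[float]] = None,
    window: float = 100.0,
    omega: float = 0.5,
    k: int = defaults.DEFAULT_K,
) -> ROCCurve:
    """Threshold-swept ROC of one method and direction on one dataset.

    For the classification method the sweep is run with leave-one-out
    cross-validation: each trial is scored by a model fitted on the other
    trials (the category statistics do not depend on the threshold, so the
    fits are reused across the sweep).
    """
    win = accept_window(direction)
    if thresholds is None:
        thresholds = defaults.default_thresholds(method, direction)

    if method != "classification":
        factory = _detector_factory(method, grid, window, omega)
        return roc_sweep(factory, trains, changes[direction], win, thresholds, direction)

    train_window = (
        defaults.TRAIN_WINDOW_INCREASE
        if direction == "increase"
        else defaults.TRAIN_WINDOW_DECREASE
    )
    dets: dict[int, ClassificationDetector] = {}
    for i, test in enumerate(trains):
        fold = [tr for j, tr in enumerate(trains) if j != i]
        model = fit_classifier(
            fold, changes[direction], omega, k, train_window, grid, direction
        )
        dets[id(test)] = ClassificationDetector(model, test, grid)
    return roc_sweep(
        lambda tr: dets[id(tr)], trains, changes[direction], win, thresholds, direction
    )


def compare_methods(
    trains: Sequence[SpikeTrain],
    changes: dict[str, np.ndarray],
    dt: float = defaults.DEFAULT_DT,
    window: float = 100.0,
    omega: float = 0.5,
    k: int = defaults.DEFAULT_K,
    methods: Sequence[str] = METHODS,
) -> dict[tuple[str, str], ROCCurve]:
    """AUC comparison of the detection methods on one dataset.

    Returns a ROC curve per (method, direction).
    """
    duration = trains[0].duration
    grid = TimeGrid(dt=dt, start=0.0, end=duration)
    out: dict[tuple[str, str], ROCCurve] = {}
    for method in methods:
        for direction in ("increase", "decrease"):
            out[(method, direction)] = method_roc(
                method, trains, changes, direction, grid,
                window=window, omega=omega, k=k,
            )
    return out


# ---------------------------------------------------------------------------
# Reference detectors for calibration of the evaluation machinery


class StratifiedRandomDetector:
    """Chance-level reference detector.

    Candidate CP times form a phase-randomized sequence with exactly one
    candidate per accepted-range length (the cadence the re-arm rule allows
    a saturated detector), each carrying an independent uniform mark; at
    threshold ``p`` the candidates with mark below ``p`` are emitted.  Every
    accepted-range window then contains exactly one candidate, selected with
    probability ``p``, so the swept normalized ROC traces the chance
    diagonal regardless of the underlying spike train (the TP/FP labeling
    uses only CP and change times).
    """

    method = "stratified_random"

    def __init__(self, duration: float, accept_len: float, rng: np.random.Generator):
        phase = rng.uniform(0.0, accept_len)
        cand = phase + accept_len * np.arange(int(duration // accept_len) + 1)
        self._cand = cand[cand < duration]
        self._mark = rng.uniform(0.0, 1.0, size=self._cand.size)

    def detect(self, direction: str, theta: float) -> DetectionResult:
        sel = np.sort(self._cand[self._mark < theta])
        return DetectionResult(direction, sel, self.method, {"p": theta})


def chance_level_auc(
    seed: int,
    n_replicates: int = 200,
    duration: float = 4250.0,
    n_changes: int = 8,
    n_thresholds: int = 21,
) -> np.ndarray:
    """AUC of randomly placed CPs against random nominal change times.

    Each replicate draws fresh nominal change times (spaced so the accept
    windows stay disjoint) and a fresh :class:`StratifiedRandomDetector`;
    returns the per-replicate AUCs, whose mean is the chance level of the
    normalized ROC (the evaluation uses only CP and change times, so the
    result holds for any underlying stationary train).
    """
    win = ACCEPT_INCREASE
    rng = np.random.default_rng(seed)
    thresholds = np.linspace(0.0, 1.0, n_thresholds)
    aucs = np.empty(n_replicates)
    for rep in range(n_replicates):
        # nominal change times with disjoint accept windows
        while True:
            chg = np.sort(rng.uniform(win.hi, duration - win.hi, size=n_changes))
            if np.all(np.diff(chg) > win.length + 1.0):
                break
        det = StratifiedRandomDetector(duration, win.length, rng)
        pts = []
        for p in thresholds:
            lab = label_cps(det.detect("increase", p), chg, win, duration)
            tp, fp = rates(lab, win)
            pts.append((fp, tp))
        aucs[rep] = auc(np.asarray(pts))
    return aucs


class OracleDetector:
    """Emits exactly one CP at ``change + 20`` ms per true change."""

    method = "oracle"

    def __init__(self, changes: np.ndarray, offset: float = 20.0):
        self._cps = np.sort(np.asarray(changes, float)) + offset

    def detect(self, direction: str, theta: float) -> DetectionResult:
        return DetectionResult(direction, self._cps.copy(), self.method, {})


def oracle_detector_auc(
    seed: int = 0, duration: float = 4250.0, n_changes: int = 6
) -> float:
    """AUC of the oracle detector (one perfectly timed CP per increase)."""
    rng = np.random.default_rng(seed)
    win = ACCEPT_INCREASE
    chg = np.sort(rng.uniform(win.hi, duration - win.hi, size=n_changes))
    while np.any(np.diff(chg) <= win.length + 1.0):
        chg = np.sort(rng.uniform(win.hi, duration - win.hi, size=n_changes))
    det = OracleDetector(chg)
    lab = label_cps(det.detect("increase", 0.5), chg, win, duration)
    tp, fp = rates(lab, win)
    return auc(np.asarray([[fp, tp]]))


def isi_ratio_omega_effect(
    seed: int,
    preset: str = "adapting",
    omegas: tuple[float, float] = (0.0, 0.5),
    n_trials: int = 10,
    dt: float = defaults.DEFAULT_DT,
    p_positive: float = 1.0,
) -> dict[float, float]:
    """Decrease-direction ISI-Ratio AUC at different ISI weights.

    With spike-frequency adaptation the last ISI before a pause is long and
    noisy; averaging in the second-last ISI stabilises the ratio's
    denominator, which is the mechanism by which a weight near 0.5 improves
    decrease detection.
    """
    trains, changes, protocol, _ = standard_dataset(
        seed, preset, n_trials=n_trials, p_positive=p_positive
    )
    grid = TimeGrid(dt=dt, start=0.0, end=protocol.duration)
    out = {}
    for w in omegas:
        curve = method_roc("isi_ratio", trains, changes, "decrease", grid, omega=w)
        out[w] = curve.auc
    return out
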