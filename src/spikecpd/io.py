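"""Plain-text file formats and the end-to-end run pipeline.

Spike trains travel as a CSV with header ``trial_id,spike_time_ms`` (one row
per spike) plus a JSON sidecar ``<name>.meta.json`` carrying the recording
duration; protocols and summaries are JSON.  Every file written by the
pipeline embeds the package version and a hash of the configuration that
produced it (CSV files as a leading ``#`` comment line).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__, defaults
from .core import ConfigurationError, SpikeTrain
from .detectors import DetectionResult
from .evaluation import ROCCurve
from .pipeline import METHODS, compare_methods, standard_dataset
from .synthetic import PRESETS, StimulusEvent, StimulusProtocol

__all__ = [
    "read_spiketrains",
    "write_spiketrains",
    "read_protocol",
    "write_protocol",
    "write_detections",
    "write_roc",
    "config_hash",
    "run_pipeline",
]


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".csv" \
        else path.with_suffix(".meta.json")


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serialisable configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _stamp(config: Optional[dict]) -> str:
    h = config_hash(config) if config else "none"
    return f"# spikecpd v{__version__} config={h}\n"


def write_spiketrains(
    trains: Sequence[SpikeTrain], path: str | Path, config: Optional[dict] = None
) -> None:
    """Write trials as CSV (trial_id, spike_time_ms) plus a JSON sidecar
    carrying the recording duration."""
    path = Path(path)
    rows = pd.DataFrame(
        {
            "trial_id": np.concatenate(
                [np.full(tr.n_spikes, tr.trial_id, dtype=int) for tr in trains]
            )
            if trains
            else np.empty(0, dtype=int),
            "spike_time_ms": np.concatenate([tr.times for tr in trains])
            if trains
            else np.empty(0),
        }
    )
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        rows.to_csv(fh, index=False)
    meta = {
        "duration_ms": trains[0].duration if trains else 0.0,
        "trial_ids": [tr.trial_id for tr in trains],
        "version": __version__,
        "config_hash": config_hash(config) if config else None,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=2))


def read_spiketrains(path: str | Path) -> list[SpikeTrain]:
    """Read spike trains written by :func:`write_spiketrains`.

    Validates per-trial ordering and reports the offending CSV row on
    duplicate or decreasing spike times.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = {"trial_id", "spike_time_ms"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"{path}: header must contain {sorted(required)}")
    meta = json.loads(_meta_path(path).read_text())
    duration = float(meta["duration_ms"])

    trains = []
    for trial_id, sub in df.groupby("trial_id", sort=True):
        times = sub["spike_time_ms"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.diff(times) <= 0)
        if bad.size:
            row = int(sub.index[bad[0] + 1]) + 2  # 1-based, after header
            raise ConfigurationError(
                f"{path}: non-increasing spike time in trial {trial_id} at row {row}"
            )
        trains.append(SpikeTrain(times=times, duration=duration, trial_id=int(trial_id)))
    return trains


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    doc = {
        "base_db": protocol.base_db,
        "duration_ms": protocol.duration,
        "n_trials": protocol.n_trials,
        "events": [
            {
                "time_ms": e.time,
                "type": e.type,
                "direction": e.direction,
                "amplitude_db": e.amplitude,
            }
            for e in protocol.events
        ],
        "version": __version__,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_protocol(path: str | Path) -> StimulusProtocol:
    doc = json.loads(Path(path).read_text())
    events = tuple(
        StimulusEvent(
            time=float(e["time_ms"]),
            type=e["type"],
            direction=e["direction"],
            amplitude=float(e["amplitude_db"]),
        )
        for e in doc["events"]
    )
    return StimulusProtocol(
        base_db=float(doc["base_db"]),
        events=events,
        duration=float(doc["duration_ms"]),
        n_trials=int(doc.get("n_trials", 10)),
    )


def write_detections(
    results: Sequence[tuple[int, DetectionResult]],
    path: str | Path,
    config: Optional[dict] = None,
) -> None:
    """Write putative CPs as CSV: trial_id, direction, cp_time_ms, method."""
    records = [
        {
            "trial_id": trial_id,
            "direction": res.direction,
            "cp_time_ms": t,
            "method": res.method,
        }
        for trial_id, res in results
        for t in res.cp_times
    ]
    df = pd.DataFrame(records, columns=["trial_id", "direction", "cp_time_ms", "method"])
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, index=False)


def write_roc(
    curves: dict[tuple[str, str], ROCCurve], path: str | Path,
    config: Optional[dict] = None,
) -> None:
    """Write swept ROC points as CSV: method, direction, theta, rates."""
    records = []
    for (method, direction), curve in curves.items():
        for theta, (fp, tp) in zip(curve.thresholds, curve.points):
            records.append(
                {
                    "method": method,
                    "direction": direction,
                    "theta": theta,
                    "fp_rate_mean": fp,
                    "tp_rate_mean": tp,
                }
            )
    df = pd.DataFrame(
        records, columns=["method", "direction", "theta", "fp_rate_mean", "tp_rate_mean"]
    )
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, index=False)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Simulate -> detect/sweep -> evaluate, writing all artifacts.

    ``config`` keys (all optional): ``seed``, ``preset``, ``n_trials``,
    ``n_steps``, ``dt``, ``window``, ``omega``, ``k``, ``methods``.
    Writes ``trains.csv`` (+ sidecar), ``protocol.json``, ``roc.csv`` and
    ``summary.json``; returns the summary dict.
    """
    cfg = {
        "seed": 0,
        "preset": "strong",
        "n_trials": 10,
        "n_steps": 6,
        "dt": defaults.DEFAULT_DT,
        "window": 100.0,
        "omega": 0.5,
        "k": defaults.DEFAULT_K,
        "methods": list(METHODS),
    }
    unknown = set(config) - set(cfg)
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    if cfg["preset"] not in PRESETS:
        raise ConfigurationError(f"unknown preset {cfg['preset']!r}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trains, changes, protocol, model = standard_dataset(
        cfg["seed"], cfg["preset"], n_trials=cfg["n_trials"], n_steps=cfg["n_steps"]
    )
    write_spiketrains(trains, out / "trains.csv", config=cfg)
    write_protocol(protocol, out / "protocol.json")

    curves = compare_methods(
        trains, changes, dt=cfg["dt"], window=cfg["window"],
        omega=cfg["omega"], k=cfg["k"], methods=cfg["methods"],
    )
    write_roc(curves, out / "roc.csv", config=cfg)

    summary = {
        "version": __version__,
        "config": cfg,
        "config_hash": config_hash(cfg),
        "auc": {
            f"{method}_{direction}": curves[(method, direction)].auc
            for (method, direction) in curves
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
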