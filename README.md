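# spikecpd

Online detection of stimulus change points from single-neuron interspike
intervals.

Sensory neurons signal changes in their environment, and a downstream reader
— or an experimenter — often needs to detect *when* a stimulus changed using
nothing but one spike train, online, without future information. This
package implements and compares four such detectors, originally motivated by
recordings from the cricket's ultrasound-sensitive auditory interneuron AN2
responding to sound-intensity steps. Intensity **increases** produce bursts
of very short interspike intervals (ISIs); **decreases** produce pauses. The
two directions are detected independently.

## The quantities and the methods

For spike times `t_1 < t_2 < …` let `s_1(t)` be the last spike at or before
`t`, and `i_1, i_2, i_3` the last completed ISIs. Everything is built from
two causal quantities:

- **adjusting ISI** `I_a(t) = max(i_1(t), t − s_1(t))` — the last ISI, taken
  over by the elapsed time since the last spike once that exceeds it; it
  grows linearly during pauses;
- **weighted previous ISI** `I_pre(t, ω) = (1−ω)·i_1 + ω·i_2` (one ISI
  further back when `t` is itself a spike time), a convex combination with
  weight `ω` on the older interval.

The four detectors, each producing putative change points (CPs) per
direction from threshold crossings:

| method | statistic | increase CP | decrease CP |
|---|---|---|---|
| Moving-Average | instantaneous rate `1/I_a(t)` vs. trailing mean ± θ·SD over `[t−W, t]` | rate above band (at spike times) | rate below band |
| Pure-ISI | `I_a(t)` | `I_a < θ_in` | `I_a > θ_de` |
| ISI-Ratio | `R(t, ω) = I_a(t) / I_pre(t, ω)` | `R < θ_in < 1` at spike times | `R > θ_de > 1` |
| Classification | relative frequency `f(C_pre, C_a)` of logarithmically binned ISI-pair categories, learned from training trials | `P(t) > θ` | `P(t) > θ` (trained per direction) |

Only the first grid point of a crossing episode is a putative CP; the
detector re-arms after a continuous crossing longer than the accepted time
range, and never emits two CPs between the same pair of spikes.

Evaluation is continuous-time: a putative CP is a true positive if it is the
first one inside the accepted latency window after a true change
(`[10, 40]` ms for increases, `[15, 55]` ms for decreases), otherwise a
false positive. Rates are normalized as

```
TP-rate = #TP / n,        FP-rate = #FP / (D/|T_accept| − n),
```

with `D` the recording duration, and threshold sweeps yield trial-averaged
ROC curves and their AUC.

A synthetic generator produces the step-protocol stimuli (50 ms positive
steps of 2–18 dB, 100 ms negative steps of 2–5 dB, every 400 ms within a
0.5–3.75 s stimulation window of a 4.25 s, 10-trial recording) and AN2-like
responses (onset bursts that adapt, activity-dependent pauses with slow
recovery) via time-rescaled gamma renewal processes, so the whole pipeline
runs without any recorded data.

## Worked example

```python
import numpy as np
from spikecpd import (TimeGrid, ThresholdPair, detect_isi_ratio,
                      label_cps, rates, ACCEPT_DECREASE)
from spikecpd.pipeline import standard_dataset, compare_methods

trains, changes, protocol, model = standard_dataset(
    seed=1, preset="strong", p_positive=1.0)

grid = TimeGrid(dt=0.1, start=0.0, end=protocol.duration)
res_in, res_de = detect_isi_ratio(
    trains[0], grid, omega=0.5, thr=ThresholdPair(theta_in=0.5, theta_de=2.0))
lab = label_cps(res_de, changes["decrease"], ACCEPT_DECREASE, protocol.duration)
tp_rate, fp_rate = rates(lab, ACCEPT_DECREASE)
print(f"trial 0 decreases: {lab.n_tp} TP, {lab.n_fp} FP "
      f"-> TP-rate {tp_rate:.2f}, FP-rate {fp_rate:.3f}")

for (method, direction), curve in sorted(compare_methods(trains, changes).items()):
    print(f"{method:>15s} {direction:<8s} AUC = {curve.auc:.3f}")
```

prints

```
trial 0 decreases: 7 TP, 23 FP -> TP-rate 1.00, FP-rate 0.232
 classification decrease AUC = 0.822
 classification increase AUC = 0.980
      isi_ratio decrease AUC = 0.851
      isi_ratio increase AUC = 0.951
 moving_average decrease AUC = 0.713
 moving_average increase AUC = 0.962
       pure_isi decrease AUC = 0.585
       pure_isi increase AUC = 0.974
```

At `θ_de = 2` the ratio method finds every pause in trial 0 at the cost of
23 false crossings over the 4.25 s trial (normalized FP-rate 0.23). The AUC
table shows the characteristic ordering on strong responses: every method
detects the burst-marked increases well (AUC ≥ 0.95 here), the ISI-Ratio and
classification methods also detect decreases well (≈ 0.82–0.85), while the
Pure-ISI threshold collapses on decreases that follow bursts (0.59): by the
time the adjusting ISI exceeds a threshold large enough to be safe against
ordinary long ISIs, the accepted window has usually closed.

The same pipeline is available from the shell:

```bash
spikecpd simulate --preset strong --trials 10 --seed 42 --out-dir data/
spikecpd detect --method isi_ratio --spikes data/trains.csv \
    --theta-in 0.5 --theta-de 2.0 --omega 0.5 --out cps.csv
spikecpd sweep --spikes data/trains.csv --protocol data/protocol.json \
    --out roc.csv --summary auc.json
spikecpd run --seed 42 --preset strong --out-dir run/   # end to end
```

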