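# Methods

This note documents the detection methods, the evaluation conventions, the
synthetic response model, and the numerical choices made in `spikecpd`, in
enough detail to reproduce or modify any of them.

## ISI quantities and warm-up

All detectors are built on causal, single-trial quantities. With `s_i(t)`
the `i`-th last spike at or before `t` (a query exactly at a spike resolves
to that spike) and `i_k` the last completed ISIs:

- `I_a(t) = i_1(t)` while `t − s_1(t) < i_1(t)`, else `t − s_1(t)`. The
  quantity needs two spikes of history; it is piecewise linear in `t` with
  slope 0 or 1 and never decreases between spikes.
- `I_pre(t, ω) = (1−ω)·i_1 + ω·i_2` strictly between spikes and
  `(1−ω)·i_2 + ω·i_3` exactly at a spike, so the interval that just ended at
  `t` never enters its own reference. Only ISIs with non-zero weight are
  required to exist (`ω = 0` needs one fewer spike).

Quantities are *partial functions*: before enough spikes have occurred they
are undefined, evaluation on a grid yields NaN there, and detectors treat
those samples as non-crossing. This warm-up masking is a package decision —
nothing in the problem fixes how the first one or two ISIs of a recording
should be treated — and it only affects the first few tens of milliseconds
of a trial.

## Grid evaluation

Continuous time is evaluated on a uniform grid, default `dt = 0.1` ms.
A crossing between grid points is assigned to the first grid point
satisfying the condition, so detected CP times carry a one-step
discretization error; a dedicated test halves `dt` and checks that no CP
appears or disappears and none moves by more than the coarse step. Grid
bins `(t − dt, t]` that contain a spike are evaluated *at that spike time*,
which matters for `I_pre`'s at-spike branch: without it the ratio
`I_a/I_pre` would collapse to 1 immediately after every spike and the
increase channel could never fire. If several spikes share one bin the last
one is used; the synthetic data keep ISIs well above `dt`.

## From threshold crossings to putative CPs

A boolean crossing series is reduced to putative CP times by three rules,
applied per direction independently (increase and decrease channels never
suppress each other):

1. only the first grid time of each maximal crossing episode counts;
2. after the episode has lasted one accepted-range length (30 ms for
   increases, 40 ms for decreases) the detector re-arms and may emit again
   every further accepted-range length — without this, an arbitrarily long
   crossing would cap the number of false positives and make ROC curves
   non-monotone in the threshold;
3. at most one CP may fall between any two consecutive spikes.

The re-arm period equals the length of the direction's own accepted range;
that choice is the only reading consistent with using the same constant for
window length, re-arm, and FP normalization.

## The four detectors

**Moving-Average.** The instantaneous rate `1/I_a(t)` is compared with its
mean ± `θ`·SD over the trailing window `[t − W, t]`, both computed from the
grid samples (population SD; a window is used only when fully covered by
defined samples). `W` defaults to 100 ms; the canonical sweep uses 17 sizes
5–200 ms. Increase CPs are restricted to spike times: an episode's CP is
deferred to the first spike-containing bin of the episode (rate increases
happen at spikes; an episode that starts between spikes reflects band
movement, not new evidence). Decrease CPs may fall between spikes. When the
window variance is exactly zero any deviation from the mean is a crossing.
Numerics: the windowed sums are computed from centered cumulative sums, and
residual variance below `1e-12·mean²` is clipped to zero; band comparisons
carry an absolute guard of `1e-9` times the rate scale so that exact-tie
samples never cross by round-off.

**Pure-ISI.** `I_a < θ_in` (fires at spike times) and `I_a > θ_de` (fires
between spikes; on a single long gap the crossing is analytically at
`s_1 + θ_de`, which the grid reproduces to within one step).

**ISI-Ratio.** `R(t, ω) = I_a(t)/I_pre(t, ω)` with `θ_in < 1 < θ_de`. The
increase channel is defined at spike times: each spike's ratio (at-spike
branch) is held over the following inter-spike interval, so an episode of
consecutive sub-threshold spikes fires once, at its first spike. The
decrease channel uses the full grid series; during a pause `I_pre` is frozen
and the crossing is analytically at `s_1 + θ_de·I_pre`. `ω` defaults to 0.5
in the comparison pipeline; the canonical sweep uses 17 weights in [0, 1].

**Classification.** A naive-Bayes-style classifier on the pair
`(C_pre, C_a)` of discretized `I_pre` and `I_a`. Category borders are
geometric between the smallest and largest training ISI,
`e_j = a·(b/a)^(j/k)` with `e_0 = 0` and `e_k = ∞`, `k = 10` by default.
Grid points inside the training window after a change of the target
direction (`[10, 40]` ms for increases; `[20, 65]` ms for decreases — the
decrease window starts later so that the burst tail preceding a late pause
does not teach the classifier that ordinary activity predicts a change)
are counted into `N_in`, all other valid points into `N_c,de`, and the
change probability of a pair is `f = N_in/(N_in + N_c,de)`. A pair never
seen in training gets `f = 0`: absence of evidence must not trigger
detection. Detection thresholds `P(t) > θ` with `θ ∈ [0, 1]` (strict, so
`θ = 1` never fires). Evaluation uses leave-one-out cross-validation over
the trials of a recording; the fits are reused across the threshold sweep
since the category statistics do not depend on `θ`.

## Evaluation

A putative CP is a true positive if it is the first inside
`[change + lo, change + hi]` for a change of its direction (increases
`[10, 40]` ms, decreases `[15, 55]` ms — configuration constants reflecting
response latencies); later CPs in the window and all CPs outside windows
are false positives. Windows of one direction must be disjoint (the
protocol generator guarantees ≥ 300 ms spacing); overlap is a configuration
error. Rates are `TP/n` and `FP/(D/|T| − n)`; the FP-rate can exceed 1.

ROC curves sweep one threshold per direction, compute per-trial rates, and
average them arithmetically across trials per threshold (no vertical
averaging). The AUC convention: sort points by FP-rate, prepend (0, 0),
extend horizontally from the largest FP-rate to 1, clip FP-rates above 1,
and integrate by the trapezoidal rule over [0, 1]. This convention makes
AUCs comparable across sweeps whose maximal FP-rates differ.

Two reference detectors calibrate the machinery. A *perfectly informed*
detector (one CP at `change + 20` ms per true change, nothing else) reaches
AUC 1.0. The *chance* reference emits candidates from a phase-randomized
sequence with exactly one uniform candidate per accepted-range length —
the cadence the re-arm rule allows a saturated detector — each kept with
probability `p`; sweeping `p` traces the diagonal and its AUC averages 0.50
(measured 0.50 ± 0.01 over 200 replicates). Unconstrained uniform CPs would
*not* score 0.5 under these normalized rates: the first-hit rule saturates
the TP-rate while false positives keep accruing, pushing the AUC to ≈ 0.4;
the rate constraint is what makes "chance" mean the diagonal.

## Synthetic stimulus and response model

The protocol generator reproduces the step-stimulation design: baseline
intensity with 50 ms positive steps (2–18 dB) and 100 ms negative steps
(2–5 dB) every 400 ms, stimulation from 0.5 to 3.75 s of a 4.25 s recording,
10 trials. Each positive step contributes an increase (IFB) and a decrease
back to baseline (DBB) 50 ms later; each negative step a decrease (DFB) and
an increase back (IBB) 100 ms later; stimulation onset and offset contribute
one change each. Same-direction changes are always ≥ 300 ms apart, so accept
windows never overlap.

The response model is a piecewise firing-rate profile driving a
time-rescaled gamma renewal process (shape 1 = inhomogeneous Poisson; the
ISI coefficient of variation at constant rate is `1/√shape`). Parameters of
`ResponseModel`, with defaults of the "strong" preset:

| parameter | default | unit | role |
|---|---|---|---|
| `baseline_rate` | 55 | spikes/s | sustained rate at baseline intensity and outside stimulation (mean baseline ISI ≈ 18 ms) |
| `gain_db` | 1.08 | ×/dB | multiplicative sustained-rate gain per dB of step |
| `onset_burst_rate` | 400 | spikes/s | transient peak after an increase (burst ISIs ≈ 2.5 ms); also sets the transient gain `β = onset_burst_rate/baseline_rate` |
| `adapt_tau` | 20 | ms | decay of the onset transient to the sustained level |
| `suppress_tau` | 10 | ms | decay of the *previous* activity after a decrease (the burst tail) |
| `recovery_tau` | 150 | ms | recovery from the suppression trough; pauses outlast the accepted range |
| `latency` | 15 | ms | delay between a stimulus change and its effect |
| `gamma_shape` | 4 | – | renewal regularity (CV 0.5) |

Increases jump (after the latency) to `max(onset_burst_rate, target)` and
adapt exponentially to the target. Decreases are *continuous*: the previous
rate decays with `suppress_tau`, undershoots into an alpha-shaped pause of
depth `(1 − 1/β)·target`, and recovers with `recovery_tau`; transients are
truncated to the target exactly after five time constants. Tying the pause
depth to the same transient gain as the burst means a model without onset
bursts produces no pauses either, and a flat drive yields an exactly
constant rate. The continuity makes the pause onset activity-dependent:
after a strong burst the tail of short ISIs fills the early accepted window
and the pause develops late, whereas a decrease from baseline pauses almost
immediately — which is exactly why an absolute-ISI threshold misses
decreases that follow bursts while the ratio (whose reference interval is
the short tail ISI) catches them, and why the slow recovery litters the
record with mid-length ISIs that are false-positive fodder for absolute
thresholds but invisible to relative ones.

Presets: `strong` (defaults above: every increase answered by a burst with
ISIs < 6.5 ms, clear pauses), `medium` (`onset_burst_rate` 100, `gain_db`
1.05: shortest post-increase ISIs in the 7–40 ms band), `weak`
(`onset_burst_rate` 0, `gain_db` 1.02: no transients, nearly flat rates),
and `adapting` (`adapt_tau` 30: response ISIs keep lengthening into the
following decrease, the regime where weighting the second-last ISI into
`I_pre` stabilizes the ratio's denominator and measurably improves decrease
detection).

What the generator does **not** emulate: serial rate correlations during
constant stimulation beyond renewal noise, trial-to-trial nonstationarity
(fatigue, adaptation across trials), amplitude-dependent burst strength and
response latency jitter, multi-unit contamination and spike-sorting errors.
Results on these data therefore establish that the implementation realizes
each method's intended behavior and their qualitative ordering under
burst/pause response statistics — not performance on any particular
recording system.

The method-comparison pipeline defaults to all-positive step protocols
(`p_positive = 1`), so that the decreases are back-to-baseline steps
following bursts — the regime in which the methods differ most; with many
decreases-from-baseline in the protocol the absolute-ISI method legitimately
recovers part of its performance.

## Numerical and degenerate-input conventions

- Time unit: milliseconds, recordings start at 0; spike times strictly
  increasing within `[0, duration]` (validated on construction).
- Random behavior: none in the detectors. The simulator takes a single
  seed and spawns independent child seeds per trial; identical seeds give
  byte-identical datasets.
- `simulate_train` integrates the rate by the trapezoidal rule and inverts
  the cumulative intensity by linear interpolation; a zero rate yields an
  empty train.
- Threshold domains are validated per method (`θ > 0` for Moving-Average
  and Pure-ISI, `θ_in < 1 < θ_de` for the ratio, `θ ∈ [0, 1]` for the
  classifier); `ω ∈ [0, 1]`.
- Classifier fitting requires at least one training trial and
  `0 < min ISI < max ISI`; leave-one-out requires at least two trials.
- Default threshold grids (`spikecpd.defaults`) are logarithmically spaced
  over each method's plausible operating range; they are sweep defaults for
  the synthetic regime, not recommendations for arbitrary recordings.

## Known limitations

- CP times are grid-quantized; sub-`dt` timing requires refining `dt`
  (cost is linear in `1/dt`).
- The Moving-Average spike-time restriction for increases is a modeling
  choice; the decrease channel is deliberately unrestricted.
- The FP normalization assumes the accepted-range length is the natural
  unit of detection opportunities; with very long recordings and sparse
  changes the FP-rate becomes insensitive to isolated false alarms.
- AUCs from different protocols are comparable only qualitatively: the
  normalization depends on `n` and `D`.
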