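# Methods

This note documents the model, the parameter choices that matter, what the
synthetic benchmark does and does not emulate, and the numerical decisions
made where the design was genuinely open.

## Model

**Neurons.** Leaky integrate-and-fire: `C dV_mem/dt = I_in − V_mem/R` with
C = 10 pF and R = 400 MΩ (membrane time constant RC = 4 ms). A neuron fires
when `V_mem` *strictly* exceeds its threshold `V_thr` (ties do not fire),
resets to `V_reset` and is clamped there for the refractory period `t_ref`.
`V_reset = 0 V` (the comparator-reset convention of analog LIF circuits)
and `t_ref = 3 ms` are package choices: neither is dictated by the
architecture, but `t_ref` must be positive because the refractory bound
`1/t_ref ≈ 333 fires/s` is what saturates the detection statistic at high
encoding gain (see the sweep behavior below). Integration is clock-driven
at `dt = 0.1 ms` with exact exponential per-step updates (input current
held constant over a step), so trajectories are robust to `dt`; halving
`dt` changes benchmark rates by well under 2%.

**Synapses.** Exponential currents, `τ_syn dI_syn/dt = −I_syn + α·W·δ(t)`:
each presynaptic spike delivers total charge `α·W` as a jump `α·W/τ_syn`.
Spike delivery carries a one-step (dt) delay from fire to postsynaptic
current, which makes the within-step update order well defined.

**Plasticity.** SDSP steps a recurrent E→E weight by `±LR_SDSP` on each
presynaptic spike arrival, by the sign of the postsynaptic membrane
relative to the learning thresholds, sampled *before* the arriving spike's
current is injected; the current then flows through the just-updated
weight. Weights clip to `[0, 2]`. Event-driven IP steps the firing
threshold by `±LR_thr` on each fire, by the calcium trace against the
healthy band, clipping to `[0.125, 0.4] V`; both learning thresholds are
re-synchronized to `V_thr/2` immediately afterwards. SDSP also fires when
the postsynaptic neuron is refractory (the clamped membrane reads as
"below the depression threshold"); this choice is switchable
(`sdsp_in_refractory`). IP applies to excitatory neurons only; inhibitory
neurons keep `V_thr = 0.2 V`.

**Calcium units.** The trace increments by +1 per spike and decays with
`τ_ip = 100 ms`, so its long-run mean is rate·τ_ip. The IP comparison uses
`(1 ± σ/2)·C_IP·τ_ip` so that `C_IP` keeps its natural units of fires/s
(equivalently: integrating the trace ODE exactly, as is done for the
synapse, makes the per-spike jump `1/τ_ip` and the trace itself a rate
estimate). A raw-comparison mode (`cip_in_rate_units=False`) is available.

**IP comparison order.** The trace is evaluated *before* the triggering
spike's increment. For near-Poisson firing, the pre-increment trace sampled
at spike times is an unbiased estimate of rate·τ_ip, so the regulated rate
lands on C_IP; including the increment adds a constant +1 — large compared
with the band half-width `σ/2·C_IP·τ_ip = 0.225` — and biases the regulated
rate down to roughly a third of the target. The post-increment variant
remains available (`ip_count_trigger_spike=True`). A residual bias exists
for *regular* firing (the trace is sampled at its troughs), which is why
the single-neuron homeostasis experiment uses a fluctuation-driven drive
(below).

## Parameters that matter

| parameter | default | why |
| --- | --- | --- |
| N_exc / N_inh | 160 / 40 | reference 80%/20% architecture |
| P_in, P_EE, P_EI, P_IE, P_II | 0.1, 5%, 2%, 10%, 0 | reference connectivity |
| N_input | 10 | base input-layer size; the input-scaling experiments raise it |
| W range, init | [0, 2], E→E = 1.0 exactly | reference values; other projections ~ U(0, 2) |
| V_thr init, range | 0.2 V, [0.125, 0.4] V | reference values |
| C_IP, σ, τ_ip | 15 fires/s, 0.3, 100 ms | homeostatic target and band |
| LR_SDSP, LR_thr | 2.0, 0.025 V | the grid corner used for the headline run; grids {0.1…2.0} × {0.025…0.3} in the sweep harness |
| F_poisson, T_bin | 150 Hz, 150 ms | encoding gain and hold duration |
| τ_syn | **150 ms** | see below |
| α | calibrated: 25 mV PSP peak at W=1 (12.5% of V_thr init) | see below |

**Why slow synapses.** The readout predicts the *next* sample from the
reservoir's current firing rates, so the network state must retain
information across `T_bin = 150 ms` sample bins. With few-ms synapses the
state decays by ~e⁻³⁰ between samples, the reservoir degenerates to a
memoryless input-follower, and one-step-ahead prediction of a sharp beat
is impossible in principle. Setting `τ_syn` of the order of the hold
duration gives each neuron an exponentially weighted memory of the recent
input/recurrent history — beat-scale fading memory. `τ_syn` and `α` are
the two constants the architecture leaves open; both are configurable.

**Why a 25 mV PSP.** With P_in = 0.1 and N_input = 10 an excitatory neuron
has on average a single input afferent and ~8 recurrent ones. If a W=1
spike moves the membrane by only a few percent of `V_thr`, the population
is provably silent — and event-driven IP, which acts only when a neuron
fires, can never bootstrap a silent neuron. The calibration helper
(`calibrate_alpha`) therefore targets a PSP peak of 12.5% of the initial
threshold at W=1 (25% at the W=2 ceiling), which keeps the network in a
fluctuation-driven, input-locked regime. Calibration was done against the
operating condition (a firing, regulable network), not against detection
scores.

**Single-neuron homeostasis experiment.** One excitatory neuron with the
reference parameters, one Poisson input at 380 Hz with W = 1 through a fast
(5 ms) synapse: mean steady-state depolarization ≈ 0.23 V, initial rate
≈ 80 fires/s at `V_thr = 0.2 V` — far above the healthy band — and the
band is reachable inside the threshold range. Stepwise IP brings the
time-averaged rate (final 20 s of a 60 s run) into the band, settling at
≈ 15 fires/s. The fast synapse keeps the drive shot-noise-like so firing
stays irregular; with slow integration the neuron bursts and the
spike-triggered trace samples are biased high.

## Synthetic benchmark

The generator emits a train of identical beats — three Gaussian bumps
(P/QRS/T-like) over a −1.8 mV baseline, 96 samples per beat at
128 samples/s, amplitudes spanning the encoder's admissible
[−2.0, +0.5] mV — plus white Gaussian noise (0.02 mV). Anomalies are
whole-beat morphology transforms with every sample of a transformed beat
labeled: `invert`, `widen`, `scale`, `drop`, `invert_widen`, and the
default `ectopic` — a premature, sub-sample-width, full-amplitude bump at
an off-schedule phase with the beat's normal complexes absent (a
premature-ventricular-contraction surrogate). The ectopic default was
chosen because a *smooth* anomaly (e.g. a widened inverted bump) is
trackable by the one-step-ahead predictor sample by sample and produces no
error peak; a temporally sharp event at an unexpected phase is precisely
what a predictor trained on the normal rhythm cannot anticipate. Its peak
amplitude equals the normal QRS sampled peak, so there is no amplitude cue.

What the generator does *not* emulate: beat-to-beat interval and amplitude
variability, baseline wander, electrode artifacts, and the annotation
conventions of real ECG databases. Consequently, a passing benchmark shows
that the reconstruction-plus-readout machinery separates sharp morphology
anomalies from a learned periodic rhythm under Poisson encoding noise — it
does not certify performance on real recordings.

**Margin bookkeeping.** `D(k+1)` compares a prediction made from sample k
with sample k+1, so the pipeline dilates each labeled event by one sample
when computing the margin and ROC ("effective labels"); the first sample
after an event reflects abnormal context and is attributed to the event.
The `judgment_margin`/`tpr_fpr_curve` operations themselves treat labels
exactly as given. TPR is reported both event-level (fraction of events
whose peak D exceeds the threshold — consistent with `TPR = 1 ⇔
D_thr < D_thr_ab`) and point-level.

**A negative result, reported deliberately.** On this clean surrogate the
*initial* (unreconstructed) network is not a failing baseline: with the
reference connectivity it saturates into a balanced high-rate state whose
E/I spread leaves a slice of neurons rate-modulated by the input, and with
slow synapses that slice is a high-signal-to-noise linear reservoir — its
margin is comparable to (sometimes better than) the reconstructed
network's. The initial-network failure seen on real long-term ECG does not
reproduce on a clean periodic toy, and we found no parameterization that
restores it without also destroying the reconstructed network's margin.
The acceptance suite asserts the expected contrast anyway and the baseline
case fails; we keep it as an honest open discrepancy rather than tune the
benchmark around it.

**Sweep behavior.** Raising the encoding gain `F_poisson` scales `F_in`
and drives the reservoir toward the refractory ceiling `1/t_ref`. In the
missing-beat (`drop`) geometry — where the anomaly peak is output-side
(the predictor announces a beat that never arrives) — `D_thr_ab` stops
scaling with the gain at the top of the sweep while `D_thr_no` keeps
growing, reproducing the ceiling-limited saturation; per-bin rates never
exceed `1/t_ref` (plus one spike of bin-edge slack).

## Numerical choices and problem sizes

* Exact exponential per-step updates for membrane, synapse and calcium;
  forward-Euler at dt/1000 and the closed-form constant-current ISI serve
  as independent oracles in the tests (agreement: spike times within one
  coarse step, ISI within 1%).
* The simulation loop is a single numba-jitted kernel; all randomness
  (connectivity, initial weights, Poisson encoding) is pre-generated from
  seeded NumPy generators outside the kernel, so runs are exactly
  reproducible given (seed, config, input).
* Ridge regularization 10⁻⁶ on the readout for conditioning only.
* Default benchmark sizes — 60 training beats, 64 test beats with 6
  anomalies, 150 ms per sample — keep a full Phase 1–3 run at ~26 M
  integration steps (≈1 min on one CPU), which we consider adequate
  sampling for the margin statistics; the sweep harness uses a 30/24-beat
  variant per cell.
* Degenerate inputs: non-positive `dt`/`T_bin` and unresolvable rates
  (`F_in·dt ≥ 1`) are rejected; out-of-range samples are clipped and
  counted; a non-finite membrane aborts the run naming the step; per-cell
  sweep failures are recorded, not fatal.

## Known limitations

* α and τ_syn are calibrated, not identified: only the qualitative regime
  (input-locked, homeostatically regulable, beat-scale memory) is pinned
  down, and detection margins shift with both.
* Event-driven IP cannot regulate a neuron that never fires; silent
  neurons keep their initial threshold indefinitely.
* The stepwise-IP set point is exact only for Poisson-like firing; regular
  or bursty firing biases the regulated rate within roughly ±30% of C_IP.
* Readout is a single abstract rectified-linear unit trained offline;
  spiking output neurons and online readout learning are out of scope, as
  are axonal delays, conductance synapses and hardware variability
  modelling.
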