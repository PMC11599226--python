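# srnn-anomaly

Anomaly detection for periodic 1-D signals (ECG-like waveforms) with a
spiking random recurrent neural network whose parameters are learned by two
hardware-friendly, *stepwise* plasticity rules:

* **Event-driven intrinsic plasticity (IP).** Each excitatory neuron keeps a
  leaky count of its own spikes (a calcium-like trace `C_fire` with
  `τ_ip dC_fire/dt = −C_fire + Σ δ(t − t_fire)`). When the neuron fires, its
  firing threshold `V_thr` is stepped up by `LR_thr` if the trace indicates a
  rate above the healthy band `(1 ± σ/2)·C_IP`, stepped down if below, and
  clipped to `[V_thr_min, V_thr_max]`. No continuous threshold control is
  needed — only a few voltage gradations.
* **Spike-driven synaptic plasticity (SDSP).** When a presynaptic spike
  arrives at a recurrent excitatory synapse, the weight is stepped by
  `±LR_SDSP` depending on whether the postsynaptic membrane sits above the
  upper or below the lower learning threshold, and clipped to `[0, W_max]`.
* **Threshold synchronization.** Because IP moves `V_thr`, fixed learning
  thresholds would break the ordering `V_LthrDOWN ≤ V_LthrUP < V_thr` that
  SDSP needs (a threshold pushed below the depression threshold drains every
  weight to zero). Both learning thresholds therefore track `V_thr/2`,
  equivalently they are stepped by `LR_thr/2` on the same trigger — this
  synchronization is what lets the two rules run concurrently.

The network is a reservoir of 160 excitatory and 40 inhibitory LIF neurons
(`C dV_mem/dt = I_in − V_mem/R`, exact exponential updates, strict-threshold
firing, refractory clamp) with random sparse connectivity
(P_EE = 5%, P_EI = 2%, P_IE = 10%, P_II = 0). Input samples `E_k` (mV) are
rate-coded as Poisson trains at

    F_in(k) = F_poisson · (4 + 2·E_k) / 5

held for `T_bin` per sample. A rectified linear readout trained by ridge
regression on the per-bin excitatory firing rates predicts the **next**
input frequency; the detection statistic is the one-step-ahead error

    D(k+1) = |F_out(k) − F_in(k+1)|.

On a labeled test segment, `D_thr_no` (largest D over normal samples) and
`D_thr_ab` (smallest over anomaly events of the event's peak D) bound the
usable detection thresholds; the judgment margin `Δ_thr = D_thr_ab − D_thr_no`
is positive exactly when some threshold detects every anomaly event with no
false positives.

The protocol has three phases: **Phase 1** reconstructs the recurrent layer
(IP + SDSP) on anomaly-free data, **Phase 2** freezes plasticity and fits
the readout, **Phase 3** evaluates D, the margin and the ROC on test data.

## Worked example

```python
from srnn_anomaly import PipelineConfig, default_benchmark, run_pipeline

train, test, labels, _ = default_benchmark(seed=0)   # 60 + 64 synthetic beats
res = run_pipeline(train, test, labels, PipelineConfig(), seed=0)
print(f"D_thr_no = {res.D_thr_no:.1f} fires/s")
print(f"D_thr_ab = {res.D_thr_ab:.1f} fires/s")
print(f"delta    = {res.delta_thr:.1f} fires/s")
tpr, _, fpr = res.rates_at(res.midpoint_threshold)
print(f"TPR = {tpr}, FPR = {fpr} at the margin midpoint")
```

prints

```
D_thr_no = 80.8 fires/s
D_thr_ab = 129.6 fires/s
delta    = 48.8 fires/s
TPR = 1.0, FPR = 0.0 at the margin midpoint
```

The training data are 60 clean periodic beats (a 3-Gaussian P/QRS/T-like
template at 128 samples/s); the test split contains 64 beats of which 6 are
ectopic-beat anomalies. The positive margin of ≈49 fires/s means every
threshold between 80.8 and 129.6 fires/s detects all 6 anomalous beats and
flags none of the ~6000 normal samples; the midpoint threshold achieves
TPR = 1.0 with FPR = 0.0. In deployment, where `D_thr_ab` is unknowable,
`res.practical_threshold(eps)` returns `D_thr_no·(1+eps)`.

The same workflow is available from the shell:

```sh
srnn-anomaly generate --out data
srnn-anomaly train   --train-csv data/train.csv --out net
srnn-anomaly readout --train-csv data/train.csv --snapshot net/network.npz --out ro
srnn-anomaly detect  --test-csv data/test.csv --snapshot net/network.npz \
                     --readout-file ro/readout.txt --out report
srnn-anomaly sweep   --train-csv data/train.csv --test-csv data/test.csv --out sweep.tsv
```

Each command writes a provenance record (config hash, seed, package
version) beside its artifacts. `--binary` switches to the 1-bit regime
(`LR_SDSP = 2.0`, `LR_thr = 0.3 V`), where weights quantize to {0, 2} and
thresholds to {0.125, 0.4} V.

## Layout

| module | contents |
| --- | --- |
| `srnn_anomaly.dynamics` | LIF membrane, exponential synapse, calcium trace, PSP calibration |
| `srnn_anomaly.plasticity` | SDSP, event-driven stepwise IP, threshold synchronization |
| `srnn_anomaly.network` | random E/I network, jitted clock-driven simulation loop, rasters |
| `srnn_anomaly.coding` | potential→rate encoding, Poisson raster generation, linear readout |
| `srnn_anomaly.anomaly` | D statistic, judgment margin, ROC, three-phase pipeline, sweeps |
| `srnn_anomaly.synthetic` | seeded beat-train generator with labeled anomalies, CSV I/O |
| `srnn_anomaly.cli` / `config` | command-line workflow, YAML configuration, provenance |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
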