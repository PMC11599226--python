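"""Random E/I network construction and the clock-driven simulation loop.

The middle layer is a randomly connected recurrent spiking network of 80%
excitatory and 20% inhibitory LIF neurons.  Input-layer neurons project to
excitatory neurons only (probability ``P_in``); excitatory neurons connect
to excitatory and inhibitory neurons with probabilities ``P_EE`` and
``P_EI``; inhibitory neurons project back to excitatory neurons with
probability ``P_IE`` and never to each other (``P_II = 0``).  Recurrent E→E
weights start at exactly 1.0 and are the only plastic synapses; all other
weights are drawn once from Uniform(0, Wmax) and stay fixed.

Simulation composes the single-neuron dynamics with the two learning rules
in a jitted clock-driven loop (see ``_kernel``); given a seed, a config and
an input spike raster the run is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from ._kernel import run_kernel
from .dynamics import NeuronParams, SynapseParams, calibrate_alpha
from .plasticity import PlasticityConfig

__all__ = [
    "NetworkConfig",
    "WeightMatrix",
    "SpikeRaster",
    "RunTrace",
    "Network",
    "build_network",
    "bin_rates",
    "simulate_ip_neuron",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and integration parameters (defaults: reference setup)."""

    N_exc: int = 160
    N_inh: int = 40
    N_input: int = 10
    P_in: float = 0.1
    P_EE: float = 0.05
    P_EI: float = 0.02
    P_IE: float = 0.10
    P_II: float = 0.0
    dt: float = 1e-4  # s
    Vthr_init: float = 0.2  # V, all neurons
    allow_autapses: bool = False

    def __post_init__(self) -> None:
        for name in ("P_in", "P_EE", "P_EI", "P_IE", "P_II"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.P_II != 0.0:
            raise ValueError("inhibitory neurons do not connect to each other (P_II must be 0)")
        if self.N_exc <= 0 or self.N_inh < 0:
            raise ValueError("need at least one excitatory neuron and N_inh >= 0")
        if self.N_input <= 0:
            raise ValueError("need at least one input neuron")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class WeightMatrix:
    """Dense per-projection weights with boolean active-synapse masks.

    Entries of inactive synapses are kept at zero; masks gate which E→E
    entries SDSP may update.
    """

    W_in: np.ndarray  # (N_input, N_exc)
    M_in: np.ndarray
    W_ee: np.ndarray  # (N_exc, N_exc)
    M_ee: np.ndarray
    W_ei: np.ndarray  # (N_exc, N_inh)
    M_ei: np.ndarray
    W_ie: np.ndarray  # (N_inh, N_exc)
    M_ie: np.ndarray

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(*(a.copy() for a in (
            self.W_in, self.M_in, self.W_ee, self.M_ee,
            self.W_ei, self.M_ei, self.W_ie, self.M_ie)))


class SpikeRaster:
    """Spike events (time, neuron index) over a simulation interval.

    Times are non-decreasing; serialization is two-column whitespace text
    ``time_s  neuron_index`` with 0-based indices.
    """

    def __init__(self, times: np.ndarray, neurons: np.ndarray, n_neurons: int, duration: float):
        times = np.asarray(times, dtype=float)
        neurons = np.asarray(neurons, dtype=np.int64)
        if times.shape != neurons.shape:
            raise ValueError("times and neurons must have the same length")
        order = np.argsort(times, kind="stable")
        self.times = times[order]
        self.neurons = neurons[order]
        self.n_neurons = int(n_neurons)
        self.duration = float(duration)

    def __len__(self) -> int:
        return len(self.times)

    def spike_times(self, neuron: int) -> np.ndarray:
        return self.times[self.neurons == neuron]

    def counts(self) -> np.ndarray:
        return np.bincount(self.neurons, minlength=self.n_neurons)

    def to_text(self, path_or_buf) -> None:
        data = np.column_stack([self.times, self.neurons.astype(float)])
        np.savetxt(path_or_buf, data, fmt=["%.7f", "%d"])

    @classmethod
    def from_text(cls, path_or_buf, n_neurons: int, duration: float) -> "SpikeRaster":
        data = np.loadtxt(path_or_buf, ndmin=2)
        if data.size == 0:
            return cls(np.empty(0), np.empty(0, dtype=np.int64), n_neurons, duration)
        return cls(data[:, 0], data[:, 1].astype(np.int64), n_neurons, duration)


@dataclass
class RunTrace:
    """Per-bin firing counts and mean excitatory threshold along a run."""

    bin_counts: np.ndarray  # (n_bins, N_exc + N_inh) spikes per bin
    T_bin: float
    n_exc: int
    vthr_mean: np.ndarray  # (n_bins,) mean excitatory Vthr at bin ends

    @property
    def rates(self) -> np.ndarray:
        """All-neuron per-bin rates in fires/s."""
        return self.bin_counts / self.T_bin

    @property
    def exc_rates(self) -> np.ndarray:
        """Excitatory per-bin rates in fires/s, shape (n_bins, N_exc)."""
        return self.bin_counts[:, : self.n_exc] / self.T_bin


class SimulationDivergedError(RuntimeError):
    """Raised when the membrane potential becomes non-finite."""

    def __init__(self, step: int):
        super().__init__(f"simulation diverged: non-finite membrane potential at step {step}")
        self.step = step


class Network:
    """A built network: parameters, weights and mutable neuron state."""

    def __init__(
        self,
        cfg: NetworkConfig,
        plast: PlasticityConfig,
        weights: WeightMatrix,
        neuron: NeuronParams = NeuronParams(),
        synapse: SynapseParams | None = None,
    ):
        self.cfg = cfg
        self.plast = plast
        self.weights = weights
        self.neuron = neuron
        # α calibrated against the reference initial threshold (0.2 V), not
        # cfg.Vthr_init: synaptic strength must not covary with the threshold
        self.synapse = synapse or SynapseParams(alpha=calibrate_alpha(params=neuron))
        # mutable state
        self.Vmem_e = np.zeros(cfg.N_exc)
        self.Vthr_e = np.full(cfg.N_exc, cfg.Vthr_init)
        self.Cfire_e = np.zeros(cfg.N_exc)
        self.refr_e = np.full(cfg.N_exc, -1, dtype=np.int64)
        self.Isyn_e = np.zeros(cfg.N_exc)
        self.Vmem_i = np.zeros(cfg.N_inh)
        self.Vthr_i = np.full(cfg.N_inh, cfg.Vthr_init)
        self.refr_i = np.full(cfg.N_inh, -1, dtype=np.int64)
        self.Isyn_i = np.zeros(cfg.N_inh)

    # -- simulation -----------------------------------------------------

    def run(
        self,
        input_raster: SpikeRaster,
        T: float,
        plasticity_on: bool = True,
        T_bin: float | None = None,
        record_spikes: bool = True,
        reset_clock: bool = True,
    ) -> tuple[SpikeRaster, RunTrace]:
        """Advance the network by ``T`` seconds driven by ``input_raster``.

        With ``plasticity_on=False`` weights and thresholds are guaranteed
        bitwise unchanged.  ``T_bin`` sets the width of the rate bins in the
        returned trace (default: one bin covering the whole run).
        """
        cfg = self.cfg
        dt = cfg.dt
        n_steps = int(round(T / dt))
        if T_bin is None:
            T_bin = T
        steps_per_bin = max(1, int(round(T_bin / dt)))
        n_bins = max(1, n_steps // steps_per_bin)

        steps = np.rint(input_raster.times / dt).astype(np.int64)
        keep = (steps >= 0) & (steps < n_steps)
        in_sp_step = steps[keep]
        in_sp_neuron = input_raster.neurons[keep].astype(np.int64)
        order = np.argsort(in_sp_step, kind="stable")
        in_sp_step = np.ascontiguousarray(in_sp_step[order])
        in_sp_neuron = np.ascontiguousarray(in_sp_neuron[order])

        if reset_clock:
            self.refr_e[:] = -1
            self.refr_i[:] = -1

        n_total = cfg.N_exc + cfg.N_inh
        if record_spikes:
            ceiling = T / (self.neuron.tref + dt)  # refractory rate bound
            cap = int(n_total * ceiling) + 1024
            if cap > 50_000_000:
                raise MemoryError(
                    "spike recording would need too large a buffer; "
                    "use record_spikes=False and the binned trace instead"
                )
        else:
            cap = 1
        rec_times = np.empty(cap)
        rec_ids = np.empty(cap, dtype=np.int64)
        bin_counts = np.zeros((n_bins, n_total), dtype=np.int32)
        vthr_bin = np.zeros(n_bins)

        p = self.plast
        c_lo, c_hi = p.cfire_band
        syn = self.synapse
        n_rec, err = run_kernel(
            n_steps,
            dt,
            steps_per_bin,
            in_sp_step,
            in_sp_neuron,
            self.weights.W_in,
            self.weights.W_ee,
            self.weights.M_ee,
            self.weights.W_ei,
            self.weights.W_ie,
            self.Vmem_e,
            self.Vthr_e,
            self.Cfire_e,
            self.refr_e,
            self.Isyn_e,
            self.Vmem_i,
            self.Vthr_i,
            self.refr_i,
            self.Isyn_i,
            np.exp(-dt / self.neuron.tau_m),
            self.neuron.R,
            np.exp(-dt / syn.tau_syn),
            np.exp(-dt / p.tau_ip),
            syn.alpha / syn.tau_syn,
            np.int64(round(self.neuron.tref / dt)),
            self.neuron.Vreset,
            bool(plasticity_on and p.sdsp_enabled),
            bool(plasticity_on and p.ip_enabled),
            p.LR_SDSP,
            p.Wmax,
            p.LR_thr,
            p.Vthr_min,
            p.Vthr_max,
            c_lo,
            c_hi,
            p.ip_count_trigger_spike,
            p.sdsp_in_refractory,
            bin_counts,
            vthr_bin,
            rec_times,
            rec_ids,
            bool(record_spikes),
        )
        if err >= 0:
            raise SimulationDivergedError(int(err))
        if n_rec < 0:
            raise RuntimeError("spike recording buffer overflowed")
        raster = SpikeRaster(rec_times[:n_rec].copy(), rec_ids[:n_rec].copy(), n_total, T)
        trace = RunTrace(bin_counts, steps_per_bin * dt, cfg.N_exc, vthr_bin)
        return raster, trace

    # -- snapshots ------------------------------------------------------

    def save(self, path) -> None:
        """Archive masks, weights and neuron state for phase hand-off."""
        meta = {
            "cfg": asdict(self.cfg),
            "plast": asdict(self.plast),
            "neuron": asdict(self.neuron),
            "synapse": {"tau_syn": self.synapse.tau_syn, "alpha": self.synapse.alpha,
                        "sign": self.synapse.sign},
        }
        w = self.weights
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            W_in=w.W_in, M_in=w.M_in, W_ee=w.W_ee, M_ee=w.M_ee,
            W_ei=w.W_ei, M_ei=w.M_ei, W_ie=w.W_ie, M_ie=w.M_ie,
            Vthr_e=self.Vthr_e, Vthr_i=self.Vthr_i, Cfire_e=self.Cfire_e,
        )

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            cfg = NetworkConfig(**meta["cfg"])
            plast = PlasticityConfig(**meta["plast"])
            neuron = NeuronParams(**meta["neuron"])
            synapse = SynapseParams(**meta["synapse"])
            weights = WeightMatrix(
                z["W_in"], z["M_in"], z["W_ee"], z["M_ee"],
                z["W_ei"], z["M_ei"], z["W_ie"], z["M_ie"],
            )
            net = cls(cfg, plast, weights, neuron, synapse)
            net.Vthr_e = z["Vthr_e"].copy()
            net.Vthr_i = z["Vthr_i"].copy()
            net.Cfire_e = z["Cfire_e"].copy()
        return net


def build_network(
    cfg: NetworkConfig,
    plast: PlasticityConfig | None = None,
    rng: np.random.Generator | int | None = None,
    neuron: NeuronParams = NeuronParams(),
    synapse: SynapseParams | None = None,
) -> Network:
    """Draw the random connectivity and initialize weights and thresholds.

    Each potential edge is an independent Bernoulli draw with its
    projection's probability.  Active E→E weights start at exactly 1.0; all
    other active weights are drawn Uniform(0, Wmax).  Autapses are excluded
    from E→E unless ``cfg.allow_autapses``.
    """
    plast = plast or PlasticityConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def proj(n_pre, n_post, p, plastic_init=None):
        mask = rng.random((n_pre, n_post)) < p
        if plastic_init is not None:
            w = np.where(mask, plastic_init, 0.0)
        else:
            w = np.where(mask, rng.uniform(0.0, plast.Wmax, (n_pre, n_post)), 0.0)
        return w, mask

    W_in, M_in = proj(cfg.N_input, cfg.N_exc, cfg.P_in)
    W_ee, M_ee = proj(cfg.N_exc, cfg.N_exc, cfg.P_EE, plastic_init=1.0)
    if not cfg.allow_autapses:
        np.fill_diagonal(M_ee, False)
        np.fill_diagonal(W_ee, 0.0)
    W_ei, M_ei = proj(cfg.N_exc, cfg.N_inh, cfg.P_EI)
    W_ie, M_ie = proj(cfg.N_inh, cfg.N_exc, cfg.P_IE)
    weights = WeightMatrix(W_in, M_in, W_ee, M_ee, W_ei, M_ei, W_ie, M_ie)
    return Network(cfg, plast, weights, neuron, synapse)


def bin_rates(raster: SpikeRaster, T_bin: float, T: float | None = None) -> np.ndarray:
    """Per-neuron per-bin firing rates (fires/s) from a spike raster.

    Returns an array of shape (n_bins, n_neurons) with n_bins = floor(T/T_bin).
    """
    if T_bin <= 0:
        raise ValueError("T_bin must be positive")
    T = raster.duration if T is None else T
    n_bins = max(1, int(T / T_bin + 1e-9))
    bins = np.minimum((raster.times / T_bin).astype(np.int64), n_bins - 1)
    counts = np.zeros((n_bins, raster.n_neurons), dtype=np.int64)
    np.add.at(counts, (bins, raster.neurons), 1)
    return counts / T_bin


def simulate_ip_neuron(
    drive_hz: float = 380.0,
    T: float = 60.0,
    seed: int | np.random.Generator = 0,
    dt: float = 1e-4,
    plast: PlasticityConfig | None = None,
    neuron: NeuronParams = NeuronParams(),
    W_in: float = 1.0,
    T_bin: float = 1.0,
    synapse: SynapseParams | None = None,
) -> RunTrace:
    """Single IP-regulated excitatory neuron under constant Poisson drive.

    The drive (one Poisson input at ``drive_hz`` with weight ``W_in``) must
    push the neuron above the healthy band at the initial threshold while
    keeping the band reachable inside the threshold bounds; the default
    (mean steady-state depolarization ≈ 0.23 V, initial rate ≈ 80 fires/s
    at V_thr = 0.2 V) keeps the regulated neuron in the fluctuation-driven
    regime, where event-driven sampling of the activity trace is least
    biased.  A fast synapse (τ_syn = 5 ms) is used by default so the drive
    is shot-noise-like and firing stays irregular; slow synaptic
    integration would make the driven neuron burst, which biases
    spike-triggered sampling of the trace.  The homeostatic
    test is whether stepwise IP brings the time-averaged rate back into
    ``(1±σ/2)·C_IP``.  Returns the per-bin trace (rates in fires/s).
    """
    from .coding import EncodingConfig, gen_input_raster  # local: avoid cycle

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    plast = plast or PlasticityConfig()
    if synapse is None:
        synapse = SynapseParams(
            tau_syn=5e-3, alpha=calibrate_alpha(0.25, params=neuron, tau_syn=5e-3))
    cfg = NetworkConfig(N_exc=1, N_inh=0, N_input=1, P_in=1.0, P_EE=0.0,
                        P_EI=0.0, P_IE=0.0, dt=dt)
    net = build_network(cfg, plast, rng, neuron=neuron, synapse=synapse)
    net.weights.W_in[:] = W_in
    net.weights.M_in[:] = True
    enc = EncodingConfig(T_bin=T_bin, dt=dt)
    n_bins = int(round(T / T_bin))
    raster = gen_input_raster(np.full(n_bins, drive_hz), enc, cfg.N_input, rng)
    _, trace = net.run(raster, T, plasticity_on=True, T_bin=T_bin, record_spikes=False)
    return trace
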