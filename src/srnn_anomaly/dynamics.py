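"""Single-neuron and single-synapse dynamics.

Leaky integrate-and-fire (LIF) membranes, exponential synaptic currents and
the calcium-like activity trace used by intrinsic plasticity.  All quantities
are in SI units (volts, amperes, seconds, farads, ohms); configuration
front-ends may use the conventional pF/MΩ/ms and convert.

The membrane obeys ``C dVmem/dt = I_in − Vmem/R``.  When ``Vmem`` strictly
exceeds the firing threshold ``Vthr`` the neuron fires, resets to ``Vreset``
and is clamped there for the refractory period ``tref``.  Synaptic currents
follow ``τ_syn dI_syn/dt = −I_syn + α·W·δ(t − t_spike)``, i.e. each
presynaptic spike delivers a total charge ``α·W`` as an instantaneous jump of
``α·W/τ_syn`` followed by exponential decay.  The calcium trace obeys
``τ_ip dC_fire/dt = −C_fire + Σ δ(t − t_fire)``; its long-run mean equals
(firing rate)·τ_ip and serves as the neuron's activity estimate.

Integration is clock-driven with *exact* exponential per-step updates (input
current held constant across one step), which makes trajectories robust to
the choice of ``dt``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "NeuronParams",
    "NeuronState",
    "SynapseParams",
    "step_membrane",
    "check_fire",
    "step_syn_current",
    "on_presyn_spike_current",
    "step_calcium",
    "psp_peak",
    "calibrate_alpha",
]


@dataclass(frozen=True)
class NeuronParams:
    """Static LIF parameters.

    Defaults are the simulation values used throughout the package:
    C = 10 pF, R = 400 MΩ (membrane time constant RC = 4 ms).
    ``Vreset`` and ``tref`` default to the comparator-reset convention
    (0 V) and 3 ms respectively.
    """

    C: float = 10e-12  # capacitance, F
    R: float = 400e6  # resistance, Ω
    Vreset: float = 0.0  # reset potential, V
    tref: float = 3e-3  # refractory duration, s
    is_excitatory: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0 or self.R <= 0:
            raise ValueError("C and R must be positive")
        if self.tref < 0:
            raise ValueError("tref must be non-negative")
        if not math.isfinite(self.C * self.R):
            raise ValueError("membrane time constant RC must be finite")

    @property
    def tau_m(self) -> float:
        """Membrane time constant RC in seconds."""
        return self.R * self.C


@dataclass
class NeuronState:
    """Mutable per-neuron state.

    ``VLthrUP``/``VLthrDOWN`` are the synaptic-plasticity learning
    thresholds, kept synchronized at ``Vthr/2`` by the plasticity layer so
    that ``VLthrDOWN ≤ VLthrUP < Vthr`` always holds.
    """

    Vmem: float = 0.0  # membrane potential, V
    Vthr: float = 0.2  # firing threshold, V
    VLthrUP: float = 0.1  # V
    VLthrDOWN: float = 0.1  # V
    Cfire: float = 0.0  # calcium trace, dimensionless
    refractory_until: float = -math.inf  # absolute time, s


@dataclass(frozen=True)
class SynapseParams:
    """Exponential-current synapse parameters.

    ``alpha`` is the charge delivered per spike at unit weight (A·s); the
    instantaneous current jump is ``sign·alpha·W/tau_syn``.  ``sign`` is +1
    for an excitatory presynaptic source and −1 for an inhibitory one.
    """

    tau_syn: float = 0.15  # s
    alpha: float = 1.035e-11  # A·s, see calibrate_alpha
    sign: int = 1

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")


def step_membrane(
    state: NeuronState, I_in: float, dt: float, params: NeuronParams, now: float = 0.0
) -> NeuronState:
    """Advance the membrane by one step of ``dt`` under constant ``I_in``.

    Uses the exact solution of the RC equation over the step:
    ``Vmem ← Vmem·e^(−dt/RC) + I_in·R·(1 − e^(−dt/RC))``.  While the neuron
    is refractory (``now < refractory_until``) the membrane stays clamped at
    ``Vreset`` regardless of the input current.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if now < state.refractory_until:
        return replace(state, Vmem=params.Vreset)
    decay = math.exp(-dt / params.tau_m)
    v = state.Vmem * decay + I_in * params.R * (1.0 - decay)
    return replace(state, Vmem=v)


def check_fire(
    state: NeuronState, params: NeuronParams, now: float
) -> tuple[bool, NeuronState]:
    """Fire iff ``Vmem`` strictly exceeds ``Vthr``; ties do not fire.

    On fire the membrane resets to ``Vreset``, the refractory clamp is armed
    until ``now + tref`` and the calcium trace receives its +1 spike
    increment.
    """
    if not state.Vmem > state.Vthr:
        return False, state
    new = replace(
        state,
        Vmem=params.Vreset,
        refractory_until=now + params.tref,
        Cfire=state.Cfire + 1.0,
    )
    return True, new


def step_syn_current(I_syn: float, dt: float, params: SynapseParams) -> float:
    """Exponential decay of the synaptic current over one step."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return I_syn * math.exp(-dt / params.tau_syn)


def on_presyn_spike_current(I_syn: float, W: float, params: SynapseParams) -> float:
    """Add one presynaptic spike's current jump ``sign·α·W/τ_syn``.

    Integrating the delta-function drive through the synapse ODE delivers a
    total charge of ``sign·α·W`` per spike, independent of ``τ_syn``.
    """
    return I_syn + params.sign * params.alpha * W / params.tau_syn


def step_calcium(Cfire: float, dt: float, tau_ip: float) -> float:
    """Decay the calcium trace; spike increments are applied in check_fire."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return Cfire * math.exp(-dt / tau_ip)


# ---------------------------------------------------------------------------
# PSP calibration
# ---------------------------------------------------------------------------

def psp_peak(
    alpha: float, W: float, params: NeuronParams, tau_syn: float
) -> float:
    """Peak membrane depolarization caused by a single spike of weight ``W``.

    Closed form for a current jump ``J = α·W/τ_syn`` decaying with τ_syn
    into an RC membrane starting from rest:
    ``V(t) = J·R·τ_syn/(τ_syn − τ_m)·(e^(−t/τ_syn) − e^(−t/τ_m))``
    evaluated at its maximum ``t* = ln(τ_syn/τ_m)/(1/τ_m − 1/τ_syn)``.
    """
    tau_m = params.tau_m
    J = alpha * W / tau_syn
    if math.isclose(tau_syn, tau_m, rel_tol=1e-9):
        # degenerate equal-time-constant limit: V(t) = J·R·(t/τ)·e^(−t/τ)
        return J * params.R / math.e
    t_star = math.log(tau_syn / tau_m) / (1.0 / tau_m - 1.0 / tau_syn)
    scale = J * params.R * tau_syn / (tau_syn - tau_m)
    return scale * (math.exp(-t_star / tau_syn) - math.exp(-t_star / tau_m))


def calibrate_alpha(
    peak_fraction: float = 0.125,
    Vthr: float = 0.2,
    params: NeuronParams | None = None,
    tau_syn: float = 0.15,
) -> float:
    """Choose α so one W=1 spike depolarizes by ``peak_fraction·Vthr``.

    Two constraints drive the defaults.  First, with the sparse
    connectivity used here an excitatory neuron has only a handful of
    afferents, so individual post-synaptic potentials must be an
    appreciable fraction of the threshold for the network to sustain
    activity at all (at a few percent the population is provably silent and
    event-driven homeostasis, which only acts on firing neurons, can never
    engage).  Second, one-step-ahead prediction of a signal presented for
    150 ms per sample requires the network state to retain history across
    samples, so the synaptic time constant must be of the order of the hold
    duration; with fast (few-ms) synapses the reservoir state decays to
    nothing between samples and carries no phase information.  The default
    pairing — τ_syn = 150 ms with a 25 mV peak (12.5% of the initial
    threshold) per W=1 spike — keeps neurons in a fluctuation-driven,
    input-locked regime with beat-scale fading memory.
    """
    if peak_fraction <= 0:
        raise ValueError("peak_fraction must be positive")
    params = params or NeuronParams()
    unit = psp_peak(1.0, 1.0, params, tau_syn)
    return peak_fraction * Vthr / unit
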