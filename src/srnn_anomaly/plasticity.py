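"""The two learning rules and their threshold synchronization.

SDSP (spike-driven synaptic plasticity): when a presynaptic spike arrives at
a plastic synapse, the weight is potentiated by ``LR_SDSP`` if the
*postsynaptic* membrane potential is above the upper learning threshold
``VLthrUP``, depressed by ``LR_SDSP`` if it is below the lower learning
threshold ``VLthrDOWN``, and left unchanged otherwise; the result is clipped
to ``[0, Wmax]``.

Event-driven stepwise IP (intrinsic plasticity): when a neuron fires, its
firing threshold is stepped up by ``LR_thr`` if the calcium activity trace
indicates firing above the healthy band ``(1±σ/2)·C_IP`` and stepped down if
below it, then clipped to ``[Vthr_min, Vthr_max]``.  No change happens inside
the band.  This realizes homeostasis with only a few threshold gradations.

Because IP moves the firing threshold, fixed learning thresholds would break
the ordering ``VLthrDOWN ≤ VLthrUP < Vthr`` that SDSP relies on (a threshold
pushed below a fixed VLthrDOWN makes every weight decay to zero).  The rules
are therefore synchronized: both learning thresholds track ``Vthr/2``,
equivalently they are stepped by ``LR_thr/2`` on the same trigger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .dynamics import NeuronState

__all__ = ["PlasticityConfig", "sdsp_update", "ip_update", "sync_thresholds"]

#: the learning-step grids explored by the sweep harness
SDSP_LR_GRID = (0.1, 0.2, 0.5, 1.0, 2.0)
THR_LR_GRID = (0.025, 0.05, 0.1, 0.3)


@dataclass(frozen=True)
class PlasticityConfig:
    """Learning-rule parameters.

    Defaults follow the reference simulation setup: weight range [0, 2] with
    initial recurrent weights 1.0, threshold range [0.125, 0.4] V around the
    initial 0.2 V, target activity C_IP = 15 fires/s with healthy-band width
    σ = 0.3, trace time constant τ_ip = 100 ms, LR_SDSP = 2.0 (binary
    weights) and LR_thr = 0.025 V.
    """

    LR_SDSP: float = 2.0
    Wmax: float = 2.0
    LR_thr: float = 0.025  # V
    Vthr_min: float = 0.125  # V
    Vthr_max: float = 0.4  # V
    C_IP: float = 15.0  # target activity, fires/s
    sigma: float = 0.3
    tau_ip: float = 0.1  # s
    sdsp_enabled: bool = True
    ip_enabled: bool = True
    #: compare Cfire against (1±σ/2)·C_IP·τ_ip (rate units for C_IP, default)
    #: instead of the raw (1±σ/2)·C_IP
    cip_in_rate_units: bool = True
    #: include the triggering spike's +1 increment in the IP comparison.
    #: Off by default: the pre-increment trace sampled at spike times is an
    #: unbiased estimate of rate·τ_ip, so the regulated rate lands on C_IP;
    #: counting the trigger adds a constant +1 bias that is large compared
    #: with the healthy band.
    ip_count_trigger_spike: bool = False
    #: apply SDSP to synapses whose postsynaptic neuron is refractory
    #: (membrane clamped at reset ⇒ depression)
    sdsp_in_refractory: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.LR_SDSP <= self.Wmax:
            raise ValueError("require 0 < LR_SDSP <= Wmax")
        if self.LR_thr <= 0:
            raise ValueError("LR_thr must be positive")
        if not 0 < self.Vthr_min < self.Vthr_max:
            raise ValueError("require 0 < Vthr_min < Vthr_max")
        if not 0 <= self.sigma < 2:
            raise ValueError("require 0 <= sigma < 2")

    @property
    def cfire_target(self) -> float:
        """Healthy-band center on the calcium-trace scale."""
        return self.C_IP * self.tau_ip if self.cip_in_rate_units else self.C_IP

    @property
    def cfire_band(self) -> tuple[float, float]:
        c = self.cfire_target
        return (1.0 - self.sigma / 2.0) * c, (1.0 + self.sigma / 2.0) * c


def sdsp_update(
    W: float,
    Vmem_post: float,
    VLthrUP: float,
    VLthrDOWN: float,
    cfg: PlasticityConfig,
) -> float:
    """One SDSP update at a presynaptic spike arrival.

    ``Vmem_post`` must be sampled before the arriving spike's own current is
    injected.  Equality with either learning threshold leaves the weight
    unchanged.
    """
    if Vmem_post > VLthrUP:
        W = W + cfg.LR_SDSP
    elif Vmem_post < VLthrDOWN:
        W = W - cfg.LR_SDSP
    return min(max(W, 0.0), cfg.Wmax)


def ip_update(state: NeuronState, cfg: PlasticityConfig) -> NeuronState:
    """One stepwise IP update, invoked when the neuron fires.

    The caller controls whether ``state.Cfire`` already contains the
    triggering spike's increment (see ``ip_count_trigger_spike``).  The
    threshold is stepped by ±``LR_thr`` outside the healthy band, clipped to
    ``[Vthr_min, Vthr_max]``, and the learning thresholds are re-synchronized
    to ``Vthr/2``.
    """
    lo, hi = cfg.cfire_band
    vthr = state.Vthr
    if state.Cfire > hi:
        vthr += cfg.LR_thr
    elif state.Cfire < lo:
        vthr -= cfg.LR_thr
    vthr = min(max(vthr, cfg.Vthr_min), cfg.Vthr_max)
    up, down = sync_thresholds(vthr)
    return replace(state, Vthr=vthr, VLthrUP=up, VLthrDOWN=down)


def sync_thresholds(Vthr: float) -> tuple[float, float]:
    """Learning thresholds slaved to the firing threshold: both = Vthr/2.

    Keeping ``VLthrDOWN ≤ VLthrUP < Vthr`` at all times is what lets SDSP and
    IP run concurrently.
    """
    half = Vthr / 2.0
    return half, half
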