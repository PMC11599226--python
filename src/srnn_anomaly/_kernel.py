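"""Clock-driven simulation kernel.

One jitted loop advances the whole recurrent network: synaptic-current and
calcium decay, spike delivery with a one-step axonal delay, SDSP on
presynaptic excitatory spike arrivals, exact-exponential membrane
integration, strict-threshold fire detection, and event-driven IP with
threshold synchronization.  The update order within a step is:

1. decay synaptic currents and calcium traces;
2. deliver spikes scheduled for this step (external input spikes and
   recurrent spikes fired in the previous step); SDSP samples the
   postsynaptic membrane *before* integration, i.e. before the arriving
   spike's current can influence it;
3. integrate membranes (refractory neurons stay clamped at reset);
4. detect fires; on each excitatory fire apply the calcium increment and,
   if enabled, the stepwise IP threshold update.

All mutable state arrays are updated in place.  The kernel is fully
deterministic: external input spikes are pre-generated and passed in as
(step, neuron) arrays.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_kernel"]


@njit(cache=True)
def run_kernel(
    n_steps,
    dt,
    steps_per_bin,
    # external input spikes, sorted by step
    in_sp_step,
    in_sp_neuron,
    # connectivity: weights (inactive entries zero) and active masks
    W_in,
    W_ee,
    M_ee,
    W_ei,
    W_ie,
    # excitatory state (in place)
    Vmem_e,
    Vthr_e,
    Cfire_e,
    refr_e,
    Isyn_e,
    # inhibitory state (in place)
    Vmem_i,
    Vthr_i,
    refr_i,
    Isyn_i,
    # dynamics constants
    decay_m,
    R,
    decay_s,
    decay_c,
    jump,
    refr_steps,
    Vreset,
    # plasticity constants / switches
    sdsp_on,
    ip_on,
    lr_sdsp,
    wmax,
    lr_thr,
    vthr_min,
    vthr_max,
    c_lo,
    c_hi,
    count_trigger,
    sdsp_in_refr,
    # outputs
    bin_counts,
    vthr_bin,
    rec_times,
    rec_ids,
    record,
):
    """Returns (n_recorded_spikes, error_step); error_step is -1 if clean.

    A non-negative error_step flags a non-finite membrane potential at that
    step (simulation diverged).  n_recorded_spikes is -1 if the recording
    buffers overflowed.
    """
    n_exc = Vmem_e.shape[0]
    n_inh = Vmem_i.shape[0]
    n_bins = bin_counts.shape[0]

    prev_fired_e = np.zeros(n_exc, np.bool_)
    prev_fired_i = np.zeros(n_inh, np.bool_)

    n_rec = 0
    cap = rec_times.shape[0]
    ip = 0  # pointer into the external spike arrays
    n_in_sp = in_sp_step.shape[0]

    for t in range(n_steps):
        # -- 1. decay ---------------------------------------------------
        for k in range(n_exc):
            Isyn_e[k] *= decay_s
            Cfire_e[k] *= decay_c
        for m in range(n_inh):
            Isyn_i[m] *= decay_s

        # -- 2. spike delivery -----------------------------------------
        # recurrent excitatory spikes from the previous step
        for j in range(n_exc):
            if not prev_fired_e[j]:
                continue
            for k in range(n_exc):
                if not M_ee[j, k]:
                    continue
                w = W_ee[j, k]
                if sdsp_on and (sdsp_in_refr or t > refr_e[k]):
                    vl = 0.5 * Vthr_e[k]
                    v = Vmem_e[k]
                    if v > vl:
                        w += lr_sdsp
                    elif v < vl:
                        w -= lr_sdsp
                    if w < 0.0:
                        w = 0.0
                    elif w > wmax:
                        w = wmax
                    W_ee[j, k] = w
                Isyn_e[k] += jump * w
            for m in range(n_inh):
                Isyn_i[m] += jump * W_ei[j, m]
        # recurrent inhibitory spikes (negative sign)
        for j in range(n_inh):
            if not prev_fired_i[j]:
                continue
            for k in range(n_exc):
                Isyn_e[k] -= jump * W_ie[j, k]
        # external input spikes scheduled for this step
        while ip < n_in_sp and in_sp_step[ip] == t:
            m = in_sp_neuron[ip]
            for k in range(n_exc):
                Isyn_e[k] += jump * W_in[m, k]
            ip += 1

        # -- 3. membrane integration -----------------------------------
        for k in range(n_exc):
            if t <= refr_e[k]:
                Vmem_e[k] = Vreset
            else:
                Vmem_e[k] = Vmem_e[k] * decay_m + Isyn_e[k] * R * (1.0 - decay_m)
        for m in range(n_inh):
            if t <= refr_i[m]:
                Vmem_i[m] = Vreset
            else:
                Vmem_i[m] = Vmem_i[m] * decay_m + Isyn_i[m] * R * (1.0 - decay_m)

        # -- 4. fire detection, calcium increment, IP ------------------
        b = t // steps_per_bin
        for k in range(n_exc):
            prev_fired_e[k] = False
            v = Vmem_e[k]
            if not np.isfinite(v):
                return n_rec, t
            if v > Vthr_e[k]:
                prev_fired_e[k] = True
                Vmem_e[k] = Vreset
                refr_e[k] = t + refr_steps
                if ip_on:
                    c_eval = Cfire_e[k] + 1.0 if count_trigger else Cfire_e[k]
                    vthr = Vthr_e[k]
                    if c_eval > c_hi:
                        vthr += lr_thr
                    elif c_eval < c_lo:
                        vthr -= lr_thr
                    if vthr < vthr_min:
                        vthr = vthr_min
                    elif vthr > vthr_max:
                        vthr = vthr_max
                    Vthr_e[k] = vthr
                Cfire_e[k] += 1.0
                if b < n_bins:
                    bin_counts[b, k] += 1
                if record:
                    if n_rec >= cap:
                        return -1, -1
                    rec_times[n_rec] = (t + 1) * dt
                    rec_ids[n_rec] = k
                    n_rec += 1
        for m in range(n_inh):
            prev_fired_i[m] = False
            v = Vmem_i[m]
            if not np.isfinite(v):
                return n_rec, t
            if v > Vthr_i[m]:
                prev_fired_i[m] = True
                Vmem_i[m] = Vreset
                refr_i[m] = t + refr_steps
                if b < n_bins:
                    bin_counts[b, n_exc + m] += 1
                if record:
                    if n_rec >= cap:
                        return -1, -1
                    rec_times[n_rec] = (t + 1) * dt
                    rec_ids[n_rec] = n_exc + m
                    n_rec += 1

        # per-bin mean excitatory threshold, sampled at the end of each bin
        if b < n_bins and (t + 1) % steps_per_bin == 0:
            s = 0.0
            for k in range(n_exc):
                s += Vthr_e[k]
            vthr_bin[b] = s / n_exc

    return n_rec, -1
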