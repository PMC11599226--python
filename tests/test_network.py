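"""Network construction and the clock-driven simulation loop."""

import math

import numpy as np
import pytest

from srnn_anomaly import (
    NetworkConfig,
    NeuronParams,
    NeuronState,
    PlasticityConfig,
    SpikeRaster,
    SynapseParams,
    Network,
    bin_rates,
    build_network,
    check_fire,
    on_presyn_spike_current,
    step_membrane,
    step_syn_current,
)


class TestBuild:
    def test_reference_population_sizes(self):
        net = build_network(NetworkConfig(), rng=0)
        assert net.Vmem_e.shape == (160,)
        assert net.Vmem_i.shape == (40,)
        assert np.all(net.Vthr_e == 0.2) and np.all(net.Vthr_i == 0.2)

    def test_plastic_weights_start_at_one_and_others_in_range(self):
        net = build_network(NetworkConfig(), rng=1)
        w = net.weights
        assert np.all(w.W_ee[w.M_ee] == 1.0)
        for arr, m in ((w.W_in, w.M_in), (w.W_ei, w.M_ei), (w.W_ie, w.M_ie)):
            assert np.all(arr[m] >= 0) and np.all(arr[m] <= 2.0)
            assert np.all(arr[~m] == 0.0)

    def test_no_autapses_by_default(self):
        net = build_network(NetworkConfig(), rng=2)
        assert not np.any(np.diag(net.weights.M_ee))

    def test_zero_probability_gives_empty_projection(self):
        net = build_network(NetworkConfig(P_EE=0.0), rng=0)
        assert not net.weights.M_ee.any()

    def test_seeded_build_is_reproducible(self):
        a = build_network(NetworkConfig(), rng=7)
        b = build_network(NetworkConfig(), rng=7)
        assert np.array_equal(a.weights.W_in, b.weights.W_in)
        assert np.array_equal(a.weights.M_ee, b.weights.M_ee)

    def test_edge_count_matches_binomial_mean(self):
        # E[active E→E] = P_EE · N(N−1); average over seeds within 4 SD
        n, p = 160, 0.05
        mean = p * n * (n - 1)
        counts = [build_network(NetworkConfig(), rng=s).weights.M_ee.sum() for s in range(20)]
        se = math.sqrt(mean * (1 - p) / 20)
        assert abs(np.mean(counts) - mean) < 4 * se

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(N_input=0)
        with pytest.raises(ValueError):
            NetworkConfig(N_exc=0)
        with pytest.raises(ValueError):
            NetworkConfig(P_II=0.5)
        with pytest.raises(ValueError):
            NetworkConfig(P_in=1.5)


def _empty_raster(n_input, T):
    return SpikeRaster(np.empty(0), np.empty(0, dtype=np.int64), n_input, T)


class TestRun:
    def test_zero_input_zero_state_emits_nothing(self, small_net_config):
        net = build_network(small_net_config, rng=0)
        raster, trace = net.run(_empty_raster(5, 1.0), 1.0)
        assert len(raster) == 0
        assert trace.bin_counts.sum() == 0

    def test_plasticity_off_freezes_weights_and_thresholds(self, small_net_config):
        net = build_network(small_net_config, rng=0)
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 2.0, 4000))
        raster = SpikeRaster(times, rng.integers(0, 5, 4000), 5, 2.0)
        w_before = net.weights.W_ee.copy()
        thr_before = net.Vthr_e.copy()
        net.run(raster, 2.0, plasticity_on=False)
        assert np.array_equal(net.weights.W_ee, w_before)
        assert np.array_equal(net.Vthr_e, thr_before)

    def test_identical_seed_identical_raster(self, small_net_config):
        rng = np.random.default_rng(5)
        times = np.sort(rng.uniform(0, 1.0, 2000))
        neurons = rng.integers(0, 5, 2000)
        out = []
        for _ in range(2):
            net = build_network(small_net_config, PlasticityConfig(), rng=3)
            raster, _ = net.run(SpikeRaster(times, neurons, 5, 1.0), 1.0)
            out.append((raster.times.copy(), raster.neurons.copy()))
        assert np.array_equal(out[0][0], out[1][0])
        assert np.array_equal(out[0][1], out[1][1])

    def test_single_pair_output_follows_input(self):
        # one input wired to one E neuron with a super-threshold weight:
        # each input spike produces one output spike at the closed-form
        # threshold-crossing time
        cfg = NetworkConfig(N_exc=1, N_inh=0, N_input=1, P_in=1.0,
                            P_EE=0, P_EI=0, P_IE=0)
        # jump 7.5 nA → I·R 3 V, decaying fast enough (τ_syn = 1 ms) that
        # the residual current cannot re-fire the neuron after refractoriness
        syn = SynapseParams(tau_syn=1e-3, alpha=7.5e-12)
        net = build_network(cfg, rng=0, synapse=syn)
        net.weights.W_in[:] = 1.0
        net.weights.M_in[:] = True
        in_times = np.array([0.05, 0.2, 0.35])
        raster, _ = net.run(SpikeRaster(in_times, np.zeros(3, dtype=np.int64), 1, 0.5), 0.5)
        assert len(raster) == 3
        delays = raster.times - in_times
        assert np.all(delays > 0) and np.all(delays < 2e-3)

    def test_kernel_agrees_with_scalar_operations(self):
        # dual route: the jitted loop vs explicit composition of the
        # single-neuron operations, same update order, same spikes
        cfg = NetworkConfig(N_exc=1, N_inh=0, N_input=1, P_in=1.0,
                            P_EE=0, P_EI=0, P_IE=0, dt=1e-4)
        syn = SynapseParams(tau_syn=5e-3, alpha=15e-12)
        neuron = NeuronParams()
        net = build_network(cfg, rng=0, neuron=neuron, synapse=syn)
        net.weights.W_in[:] = 1.0
        net.weights.M_in[:] = True
        rng = np.random.default_rng(8)
        steps = np.sort(rng.choice(5000, size=400, replace=False))
        raster = SpikeRaster(steps * cfg.dt, np.zeros(400, dtype=np.int64), 1, 0.5)
        out, _ = net.run(raster, 0.5, plasticity_on=False)
        kernel_steps = set(np.rint(out.times / cfg.dt).astype(int))

        s = NeuronState(Vmem=0.0, Vthr=0.2)
        i_syn = 0.0
        spike_steps = set(steps.tolist())
        scalar_steps = set()
        refr_steps = round(neuron.tref / cfg.dt)
        refr_left = 0  # integer-step refractory clock, matching the kernel
        for t in range(5000):
            i_syn = step_syn_current(i_syn, cfg.dt, syn)
            if t in spike_steps:
                i_syn = on_presyn_spike_current(i_syn, 1.0, syn)
            if refr_left > 0:
                refr_left -= 1
                continue
            s = step_membrane(s, i_syn, cfg.dt, neuron)
            fired, s = check_fire(s, neuron, now=(t + 1) * cfg.dt)
            if fired:
                scalar_steps.add(t + 1)
                refr_left = refr_steps
                s.refractory_until = -np.inf  # clock handled by refr_left
        assert kernel_steps == scalar_steps

    def test_no_raster_violates_refractory_period(self, small_net_config):
        net = build_network(small_net_config, rng=0)
        rng = np.random.default_rng(1)
        times = np.sort(rng.uniform(0, 2.0, 6000))
        raster, _ = net.run(SpikeRaster(times, rng.integers(0, 5, 6000), 5, 2.0), 2.0)
        for n in range(raster.n_neurons):
            isi = np.diff(raster.spike_times(n))
            assert np.all(isi >= net.neuron.tref - 1e-9)

    def test_removing_inhibition_never_reduces_excitatory_rates(self, small_net_config):
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0, 2.0, 6000))
        neurons = rng.integers(0, 5, 6000)
        counts = []
        for zero_inh in (False, True):
            net = build_network(small_net_config, rng=11)
            if zero_inh:
                net.weights.W_ie[:] = 0.0
            raster, _ = net.run(SpikeRaster(times, neurons, 5, 2.0), 2.0,
                                plasticity_on=False)
            counts.append(raster.counts()[: small_net_config.N_exc].sum())
        assert counts[1] >= counts[0]

    def test_halving_dt_changes_rates_by_under_two_percent(self):
        # same physical input spike times presented at both resolutions
        from srnn_anomaly import EncodingConfig, encode_rate, gen_input_raster
        from srnn_anomaly.synthetic import WaveformSpec, generate

        series, _ = generate(WaveformSpec(n_beats=4, seed=5))
        enc = EncodingConfig()
        rates = encode_rate(np.asarray(series), enc)
        raster = gen_input_raster(rates, enc, 10, np.random.default_rng(3))
        T = len(rates) * enc.T_bin
        traces = []
        for dt in (1e-4, 5e-5):
            net = build_network(NetworkConfig(dt=dt), rng=9)
            _, tr = net.run(raster, T, plasticity_on=False, record_spikes=False,
                            T_bin=enc.T_bin)
            traces.append(tr.exc_rates.mean())
        assert traces[1] == pytest.approx(traces[0], rel=0.02)

    def test_divergence_is_reported_with_step(self, small_net_config):
        from srnn_anomaly.network import SimulationDivergedError

        net = build_network(small_net_config, rng=0)
        net.Vmem_e[0] = np.nan
        with pytest.raises(SimulationDivergedError):
            net.run(_empty_raster(5, 0.01), 0.01)


class TestRaster:
    def test_bin_rates_example(self):
        r = SpikeRaster(np.array([0.01, 0.05, 0.10]), np.zeros(3, dtype=np.int64), 2, 0.15)
        rates = bin_rates(r, 0.15)
        assert rates.shape == (1, 2)
        assert rates[0, 0] == pytest.approx(20.0)

    def test_empty_raster_zero_rates(self):
        r = SpikeRaster(np.empty(0), np.empty(0, dtype=np.int64), 3, 1.0)
        assert np.all(bin_rates(r, 0.1) == 0)

    def test_rate_conservation(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 1.0, 500))
        r = SpikeRaster(times, rng.integers(0, 4, 500), 4, 1.0)
        rates = bin_rates(r, 0.1)
        assert rates.sum() * 0.1 == pytest.approx(500)

    def test_text_round_trip(self, tmp_path):
        r = SpikeRaster(np.array([0.1, 0.2, 0.35]), np.array([2, 0, 1]), 3, 1.0)
        p = tmp_path / "raster.txt"
        r.to_text(p)
        back = SpikeRaster.from_text(p, 3, 1.0)
        assert np.allclose(back.times, r.times)
        assert np.array_equal(back.neurons, r.neurons)

    def test_invalid_bin_width(self):
        r = SpikeRaster(np.empty(0), np.empty(0, dtype=np.int64), 1, 1.0)
        with pytest.raises(ValueError):
            bin_rates(r, 0.0)


def test_snapshot_round_trip(tmp_path, small_net_config):
    net = build_network(small_net_config, rng=4)
    net.Vthr_e[:] = 0.3
    p = tmp_path / "net.npz"
    net.save(p)
    back = Network.load(p)
    assert np.array_equal(back.weights.W_ee, net.weights.W_ee)
    assert np.array_equal(back.Vthr_e, net.Vthr_e)
    assert back.cfg == net.cfg
    assert back.synapse.alpha == net.synapse.alpha
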