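"""Spiking network: kernel correctness, single-neuron validation, biases."""

from dataclasses import replace

import numpy as np
import pytest

from striatal_dtt.dtt import find_dtt
from striatal_dtt.experiments import mip_event_input
from striatal_dtt.spiking import (
    CorticalDrive,
    FSI_PARAMS,
    MSN_PARAMS,
    NetworkConfig,
    NeuronParams,
    SpikeRecord,
    SynapseSpec,
    alpha_kernel,
    build_network,
    delta_msn_spiking,
    dtt_sweep_spiking,
    fi_curve,
    lif_rate_closed_form,
    lif_rheobase,
    population_rate,
    simulate,
)

MINI = NetworkConfig(n_d1=20, n_d2=20, n_fsi=2)


class TestAlphaKernel:
    def test_causal(self):
        assert alpha_kernel(2.5, 0.3, -1e-6) == 0.0
        assert np.all(alpha_kernel(2.5, 0.3, np.linspace(-5, -0.01, 10)) == 0.0)

    def test_peak_at_tau(self):
        assert alpha_kernel(2.5, 0.3, 0.3) == pytest.approx(2.5)
        t = np.linspace(0, 3, 3001)
        assert np.max(alpha_kernel(2.5, 0.3, t)) <= 2.5 + 1e-12

    def test_value_at_twice_tau(self):
        assert alpha_kernel(1.0, 2.0, 4.0) == pytest.approx(2.0 * np.exp(-1.0))


class TestBuildNetwork:
    def test_zero_probability_gives_no_synapses(self):
        cfg = replace(
            MINI,
            synapses=tuple(replace(s, probability=0.0) for s in MINI.synapses),
        )
        assert build_network(cfg, seed=0).n_synapses == 0

    def test_no_autapses_no_multapses(self):
        net = build_network(MINI, seed=1)
        n = MINI.n_total
        pairs = set()
        for i in range(n):
            for s in range(net.indptr[i], net.indptr[i + 1]):
                assert net.targets[s] != i
                assert (i, net.targets[s]) not in pairs
                pairs.add((i, int(net.targets[s])))

    def test_in_degree_matches_binomial_expectation(self, full_network):
        # D1 -> D1 row: p=0.26 over 1999 eligible sources
        deg = np.bincount(
            full_network.targets[full_network.peaks == 0.5],
            minlength=full_network.config.n_total,
        )[:2000]
        expect = 0.26 * 1999
        sem = np.sqrt(0.26 * 0.74 * 1999 / 2000)
        assert deg.mean() == pytest.approx(expect, abs=3 * sem)

    def test_fsi_receive_no_striatal_inhibition(self):
        with pytest.raises(ValueError):
            NetworkConfig(synapses=(SynapseSpec("d1", "fsi", 0.1, 1.0, 1.0),))

    def test_connectivity_determinism(self):
        a, b = build_network(MINI, seed=7), build_network(MINI, seed=7)
        c = build_network(MINI, seed=8)
        assert np.array_equal(a.targets, b.targets)
        assert not np.array_equal(a.targets, c.targets)


class TestSimulate:
    def test_no_input_no_spikes_relaxes_to_rest(self):
        net = build_network(MINI, seed=0)
        rec = simulate(
            net, CorticalDrive(rate=0.0, rate_fsi=0.0), T=300.0, seed=0,
            record_v_ids=[0],
        )
        assert rec.ids.size == 0
        assert rec.v_traces[0, -1] == pytest.approx(MSN_PARAMS.v_rest, abs=1e-6)

    def test_subthreshold_current_never_spikes(self):
        rates = fi_curve(MSN_PARAMS, [lif_rheobase(MSN_PARAMS) - 5.0], T=1000.0,
                         dt=0.05)
        assert rates[0] == 0.0

    def test_suprathreshold_rate_matches_closed_form(self):
        currents = [450.0, 550.0, 700.0]
        rates = fi_curve(MSN_PARAMS, currents, T=2000.0, dt=0.01)
        for i, r in zip(currents, rates):
            assert r == pytest.approx(lif_rate_closed_form(MSN_PARAMS, i), abs=1.0)

    def test_fi_curve_monotone_above_rheobase(self):
        currents = np.arange(450.0, 800.0, 50.0)
        rates = fi_curve(MSN_PARAMS, currents, T=1000.0, dt=0.02)
        assert np.all(np.diff(rates) > 0)

    def test_refractory_invariant(self):
        # drive the mini network hard and verify no ISI below t_ref
        net = build_network(MINI, seed=2)
        rec = simulate(net, CorticalDrive(rate=40.0), T=1000.0, seed=2)
        assert rec.ids.size > 100
        for i in np.unique(rec.ids):
            isi = np.diff(rec.times[rec.ids == i])
            if isi.size:
                assert isi.min() >= 2.0

    def test_delay_fidelity(self):
        """An isolated presynaptic spike perturbs the target only after the
        projection delay (2 ms for MSN->MSN rows)."""
        cfg = NetworkConfig(
            n_d1=1, n_d2=1, n_fsi=1,
            synapses=(SynapseSpec("d1", "d2", 1.0, 1.0, 2.0),),
        )
        cfg0 = replace(cfg, synapses=(SynapseSpec("d1", "d2", 0.0, 1.0, 2.0),))
        quiet = CorticalDrive(rate=0.0, rate_fsi=0.0)
        i_ext = np.array([600.0, 0.0, 0.0])
        kw = dict(T=50.0, dt=0.1, seed=5, i_ext=i_ext, record_v_ids=[1])
        rec1 = simulate(build_network(cfg, seed=0), quiet, **kw)
        rec0 = simulate(build_network(cfg0, seed=0), quiet, **kw)
        t_spike = rec1.times[rec1.ids == 0][0]
        diff = np.flatnonzero(rec1.v_traces[0] != rec0.v_traces[0])
        assert diff.size > 0
        t_effect = (diff[0] + 1) * 0.1
        assert t_effect == pytest.approx(t_spike + 2.0, abs=0.21)

    def test_input_seed_determinism(self):
        net = build_network(MINI, seed=3)
        a = simulate(net, CorticalDrive(), T=300.0, seed=4)
        b = simulate(net, CorticalDrive(), T=300.0, seed=4)
        c = simulate(net, CorticalDrive(), T=300.0, seed=5)
        assert np.array_equal(a.times, b.times) and np.array_equal(a.ids, b.ids)
        assert not np.array_equal(a.times, c.times)

    def test_dt_convergence_with_frozen_input(self):
        """Halving dt changes population rates by < 2% (event-driven input,
        silent FSIs, so the input realization is identical)."""
        cfg = NetworkConfig(n_d1=400, n_d2=400, n_fsi=2)
        ev_t, ev_a = mip_event_input(cfg, 10.0, 0.1, 0.2, 1200.0, seed=9)
        drive = CorticalDrive(rate=0.0, rate_fsi=0.0)
        rates = {}
        for dt in (0.1, 0.05):
            net = build_network(cfg, seed=9)
            rec = simulate(net, drive, T=1200.0, dt=dt, seed=9,
                           event_times=ev_t, event_amps=ev_a)
            r1, _, _ = population_rate(rec, "d1", discard=200.0)
            r2, _, _ = population_rate(rec, "d2", discard=200.0)
            rates[dt] = (r1, r2)
        for k in range(2):
            assert rates[0.05][k] > 0.5
            assert abs(rates[0.1][k] - rates[0.05][k]) / rates[0.05][k] < 0.02


def _synthetic_record(ids, times, duration, n=(2000, 2000, 80)):
    return SpikeRecord(
        ids=np.asarray(ids, dtype=np.int32),
        times=np.asarray(times, dtype=float),
        duration=duration,
        dt=0.1,
        config=NetworkConfig(n_d1=n[0], n_d2=n[1], n_fsi=n[2]),
    )


class TestRateEstimation:
    def test_one_spike_per_neuron_is_one_hz(self):
        ids = np.arange(2000)
        times = np.linspace(500.1, 1499.9, 2000)
        rec = _synthetic_record(ids, times, duration=1500.0)
        rate, psth, edges = population_rate(rec, "d1", window=10.0, discard=500.0)
        assert rate == pytest.approx(1.0)
        # PSTH conservation: sum * bin * neurons = spike count
        assert np.sum(psth) * (10.0 / 1000.0) * 2000 == pytest.approx(2000)

    def test_unbiased_for_poisson_replay(self):
        from striatal_dtt.correlated_inputs import poisson_train

        est = []
        for s in range(10):
            rng = np.random.default_rng(s)
            ids, times = [], []
            for i in range(200):
                t = poisson_train(5.0, 2000.0, rng)
                ids += [i] * t.size
                times += list(t)
            rec = _synthetic_record(ids, times, duration=2000.0, n=(200, 200, 80))
            r, _, _ = population_rate(rec, "d1", discard=0.0)
            est.append(r)
        sem = np.std(est, ddof=1) / np.sqrt(len(est))
        assert np.mean(est) == pytest.approx(5.0, abs=2 * sem + 0.01)

    def test_identical_populations_give_zero_delta(self):
        rng = np.random.default_rng(0)
        ids1 = rng.integers(0, 2000, 5000)
        times = rng.uniform(500.0, 2500.0, 5000)
        ids = np.concatenate([ids1, ids1 + 2000])
        rec = _synthetic_record(ids, np.concatenate([times, times]), 2500.0)
        d, (lo, hi) = delta_msn_spiking(rec, seed=0)
        assert d == 0.0
        assert lo <= 0.0 <= hi

    def test_empty_record_rate_zero(self):
        rec = _synthetic_record([], [], duration=1000.0)
        rate, psth, _ = population_rate(rec, "d2", discard=0.0)
        assert rate == 0.0 and np.all(psth == 0.0)


class TestNetworkBiases:
    def test_equal_drive_favours_d2(self, full_config):
        """Equal cortical gains and rates: the asymmetric connectivity biases
        the network toward D2 (checked over 3 seeds)."""
        for s in range(3):
            net = build_network(full_config, seed=1000 + s)
            rec = simulate(
                net, CorticalDrive(rate=20.0, peak_d1=3.0, peak_d2=3.0),
                T=1500.0, seed=s,
            )
            r1, _, _ = population_rate(rec, "d1", discard=500.0)
            r2, _, _ = population_rate(rec, "d2", discard=500.0)
            assert r2 > r1

    def test_zero_drive_sweep_has_no_crossing(self):
        res = dtt_sweep_spiking(
            MINI, CorticalDrive(rate_fsi=0.0, peak_d1=0.0, peak_d2=0.0),
            grid=[0.0, 1.0, 2.0], seeds=(0,), T=400.0, discard=100.0,
        )
        assert res.n_crossings == 0 and res.dtt is None

    def test_distinct_fi_curves_keep_the_transition(self, full_config):
        """With D2 MSNs given different passive properties (more excitable),
        the additive-scenario sweep still crosses from D1 to D2 exactly once."""
        cfg = replace(
            full_config, d2_params=NeuronParams(c=180.0, g_rest=11.5)
        )
        drive = CorticalDrive(rate=10.0, extra_rate_d1=2.0, peak_d1=3.0,
                              peak_d2=3.0)
        grid = [5.0, 10.0, 15.0, 20.0, 25.0, 30.0]
        vals = []
        for rate in grid:
            net = build_network(cfg, seed=1001)
            rec = simulate(net, replace(drive, rate=rate), T=1200.0, seed=1)
            d, _ = delta_msn_spiking(rec, discard=400.0, seed=1)
            vals.append(d)
        res = find_dtt(grid, vals)
        assert res.n_crossings == 1
        assert res.direction == "pos_to_neg"
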