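"""Simulator micro-oracles: leak relaxation, closed-form LIF rate, synaptic
jump-and-decay, refractoriness, gating bounds, determinism, raster IO."""

import numpy as np
import pytest

from spikescape import (Network, NetworkConfig, StimulusSpec, SpikeRaster,
                        run_trial)
from spikescape.network import _seed_numba

TINY = NetworkConfig(w_plus=1.61, N_E=40, N_I=10)  # 6/6/28/10 neurons
SMALL = NetworkConfig(w_plus=1.61, scale=8)        # 30/30/140/50 neurons


def _silent_network(config=TINY):
    """Network with recurrent conductances zeroed: isolated neurons."""
    net = Network(config)
    net.g_rec_a[:] = 0.0
    net.g_nmda[:] = 0.0
    net.g_gaba[:] = 0.0
    return net


def test_leak_relaxation_to_rest():
    """With no synaptic input V relaxes to V_L with time constant C_m/g_L."""
    net = _silent_network()
    state = net.init_state()
    state.V[:] = -60.0
    lam = np.zeros(net.config.N_total)
    _seed_numba(0)
    net.step(state, n_steps=int(10.0 / net.config.dt), lam=lam)  # 10 ms
    tau = np.where(net.is_exc, 20.0, 10.0)
    expected = -70.0 + 10.0 * np.exp(-10.0 / tau)
    assert np.allclose(state.V, expected, atol=1e-6)


def test_constant_current_isi_matches_closed_form():
    """Suprathreshold constant current: ISI = tau_ref + tau_m ln((Vinf-Vr)/(Vinf-Vth))."""
    net = _silent_network()
    i0 = 600.0  # pA -> Vinf = -70 + 600/25 = -46 mV for excitatory cells
    net.I_inj[0] = i0
    p = net.config.neuron_E
    v_inf = p.V_L + i0 / p.g_L
    isi_theory = p.tau_ref + p.tau_m * np.log(
        (v_inf - p.V_reset) / (v_inf - p.V_th))
    _seed_numba(0)
    state = net.init_state()
    flags = net.step(state, n_steps=int(2000.0 / net.config.dt),
                     lam=np.zeros(net.config.N_total))
    spike_steps = np.flatnonzero(flags[:, 0])
    assert len(spike_steps) > 50
    isi = np.diff(spike_steps) * net.config.dt
    assert np.ptp(isi) < 2 * net.config.dt  # deterministic firing
    assert isi.mean() == pytest.approx(isi_theory, rel=0.01)
    assert flags[:, 1:].sum() == 0  # nobody else fires


def test_spike_increments_gating_then_exponential_decay():
    """A spike adds 1 to the source AMPA gating, which decays with tau=2 ms."""
    net = _silent_network()
    state = net.init_state()
    state.V[0] = -49.95  # just above threshold: spikes at the first step
    lam = np.zeros(net.config.N_total)
    _seed_numba(0)
    flags = net.step(state, 1, lam=lam)
    assert flags[0, 0] == 1
    assert state.V[0] == pytest.approx(-55.0)  # reset
    assert state.s_ampa[0] == pytest.approx(1.0)
    assert state.x_nmda[0] == pytest.approx(1.0)
    net.step(state, int(2.0 / net.config.dt), lam=lam)  # 2 ms later
    assert state.s_ampa[0] == pytest.approx(np.exp(-1.0), rel=1e-3)
    net.step(state, int(2.0 / net.config.dt), lam=lam)
    assert state.s_ampa[0] == pytest.approx(np.exp(-2.0), rel=1e-3)


def test_refractory_clamp_on_raster():
    """No neuron's inter-spike interval may undercut its refractory period."""
    raster = run_trial(SMALL, StimulusSpec(mu=58), duration=1000.0, seed=5)
    tau_ref = np.where(raster.pop_of_neuron < 3, 2.0, 1.0)
    order = np.lexsort((raster.times, raster.neuron_ids))
    ids, ts = raster.neuron_ids[order], raster.times[order]
    same = ids[1:] == ids[:-1]
    isi = (ts[1:] - ts[:-1])[same]
    limits = tau_ref[ids[1:][same]]
    assert np.all(isi >= limits - 1e-9)


def test_gating_invariants_under_drive():
    """All gating variables stay non-negative and s_NMDA saturates below 1."""
    net = Network(SMALL)
    _seed_numba(3)
    state = net.init_state()
    stim = StimulusSpec(mu=58)
    for _ in range(10):  # 10 x 50 ms with invariant checks in between
        net.step(state, int(50.0 / net.config.dt),
                 lam=net.external_rates(stim, state.t))
        for arr in (state.s_ampa_ext, state.s_ampa, state.x_nmda,
                    state.s_gaba):
            assert arr.min() >= 0.0
        assert state.s_nmda.min() >= 0.0
        assert state.s_nmda.max() <= 1.0 + 1e-9
        refr = state.ref_until > state.t + 1e-12
        assert np.allclose(state.V[refr], -55.0)


def test_seed_reproducibility_and_sensitivity():
    a = run_trial(SMALL, StimulusSpec(mu=20), duration=300.0, seed=42)
    b = run_trial(SMALL, StimulusSpec(mu=20), duration=300.0, seed=42)
    c = run_trial(SMALL, StimulusSpec(mu=20), duration=300.0, seed=43)
    assert np.array_equal(a.neuron_ids, b.neuron_ids)
    assert np.array_equal(a.times, b.times)
    assert not (len(a.times) == len(c.times)
                and np.array_equal(a.times, c.times))


def test_spontaneous_rates_are_a_few_hertz():
    raster = run_trial(SMALL, None, duration=1500.0, seed=9)
    rates = raster.mean_rates()
    for pop in ("S1", "S2", "NS"):
        assert 0.2 < rates[pop] < 10.0
    assert rates["I"] < 25.0


def test_raster_roundtrip(tmp_path):
    raster = run_trial(TINY, None, duration=200.0, seed=1)
    h5 = tmp_path / "r.h5"
    raster.to_hdf5(h5)
    back = SpikeRaster.from_hdf5(h5)
    assert np.array_equal(back.neuron_ids, raster.neuron_ids)
    assert np.allclose(back.times, raster.times)
    assert back.duration == raster.duration

    csv = tmp_path / "r.csv"
    raster.to_csv(csv)
    back2 = SpikeRaster.from_csv(csv)
    assert np.array_equal(back2.neuron_ids, raster.neuron_ids)
    assert np.allclose(back2.times, raster.times)
    assert np.array_equal(back2.pop_of_neuron, raster.pop_of_neuron)
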