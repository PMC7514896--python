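"""Membrane, receptor, drive and plasticity mechanics of the simulator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import trisyn
from trisyn.config import DriveSpec, LTPParams, NetworkConfig
from trisyn.dynamics import drive_rate, generate_drive_trains
from trisyn.network import _cell

THETA_PERIOD = 125.0


# --- NMDA gating -----------------------------------------------------------

def test_nmda_gating_asymptotes():
    assert trisyn.nmda_gating(-1000.0) < 1e-3
    assert trisyn.nmda_gating(200.0) > 0.99


def test_nmda_gating_ordering():
    assert trisyn.nmda_gating(-60.0) < trisyn.nmda_gating(0.0) < trisyn.nmda_gating(40.0)


@given(st.floats(-120, 60), st.floats(0.1, 30))
@settings(deadline=None, max_examples=50)
def test_nmda_gating_monotone(v, dv):
    assert trisyn.nmda_gating(v + dv) >= trisyn.nmda_gating(v)


def test_nmda_gating_rejects_nonfinite():
    with pytest.raises(ValueError):
        trisyn.nmda_gating(float("nan"))


# --- drives ---------------------------------------------------------------

def test_drive_trains_contained_and_seeded():
    spec = DriveSpec(source="EC2", mean_rate=40.0, seed=7, deterministic=False)
    trains = generate_drive_trains(spec, 4, 2000.0, 0.1)
    again = generate_drive_trains(spec, 4, 2000.0, 0.1)
    for a, b in zip(trains, again):
        np.testing.assert_array_equal(a, b)
        assert a.size == 0 or (a.min() >= 0 and a.max() < 2000.0)


def test_drive_trains_tiny_rate():
    spec = DriveSpec(source="EC2", mean_rate=0.0001, seed=0, deterministic=False)
    trains = generate_drive_trains(spec, 3, 1000.0, 0.1)
    for t in trains:
        assert t.size >= 0
        assert np.all((t >= 0) & (t < 1000.0))


def test_drive_requires_one_theta_period():
    spec = DriveSpec(source="EC2", theta_frequency=8.0)
    with pytest.raises(ValueError):
        generate_drive_trains(spec, 1, 100.0, 0.1)


def test_ec2_ec3_antiphase_poisson():
    """Circular mean phases of the two entorhinal streams differ by ~pi."""
    def mean_phase(offset, seed):
        spec = DriveSpec(source="EC2", theta_phase_offset=offset, mean_rate=60.0,
                         seed=seed, deterministic=False)
        spikes = np.concatenate(generate_drive_trains(spec, 8, 10000.0, 0.1))
        ph = 2 * np.pi * (spikes % THETA_PERIOD) / THETA_PERIOD
        return np.angle(np.mean(np.exp(1j * ph)))

    diff = abs(mean_phase(np.pi, 1) - mean_phase(0.0, 0))
    diff = min(diff, 2 * np.pi - diff)
    assert abs(diff - np.pi) < 0.3


def test_drive_spectrum_peaks_in_theta_band():
    spec = DriveSpec(source="EC2", theta_frequency=8.0, mean_rate=60.0, seed=3,
                     deterministic=False)
    spikes = np.concatenate(generate_drive_trains(spec, 8, 30000.0, 0.1))
    binned, _ = np.histogram(spikes, bins=int(30000 / 2))  # 2 ms bins
    binned = binned - binned.mean()
    freqs = np.fft.rfftfreq(binned.size, d=0.002)
    power = np.abs(np.fft.rfft(binned)) ** 2
    band = (freqs > 1.0) & (freqs < 60.0)
    peak = freqs[band][np.argmax(power[band])]
    assert 4.0 <= peak <= 12.0


def test_pacemaker_deterministic_and_rate_matched():
    spec = DriveSpec(source="EC2", mean_rate=64.0, seed=0, deterministic=True)
    t1 = generate_drive_trains(spec, 3, 5000.0, 0.1)
    spec2 = DriveSpec(source="EC2", mean_rate=64.0, seed=99, deterministic=True)
    t2 = generate_drive_trains(spec2, 3, 5000.0, 0.1)
    for a, b in zip(t1, t2):
        np.testing.assert_array_equal(a, b)  # the pacemaker is a clock
    rate = t1[0].size / 5.0
    assert abs(rate - 64.0) / 64.0 < 0.1


def test_drive_rate_nonnegative_and_periodic():
    spec = DriveSpec(source="EC2", mean_rate=50.0)
    t = np.arange(0.0, 250.0, 0.5)
    r = drive_rate(spec, t)
    assert np.all(r >= 0)
    np.testing.assert_allclose(r[:250], r[250:], atol=1e-8)  # 125 ms periodic


# --- passive membrane dynamics --------------------------------------------

def _quiet_config(duration=500.0):
    cfg = trisyn.build_default_network(seed=0, duration=duration)
    for d in cfg.drives:
        d.mean_rate = 0.0
    cfg.init_perturbation_mv = 0.0
    return cfg


def test_silent_network_stays_at_rest():
    cfg = _quiet_config()
    res = trisyn.integrate_network(cfg)
    for cid, v in res.voltage_traces.items():
        assert np.max(np.abs(v + 65.0)) < 0.1
        assert res.spike_times[cid].size == 0


def test_step_response_matches_rc_charging():
    """Soma of an uncoupled compartment follows the analytic RC curve."""
    cell = _cell("C1", "pyramidal", "CA3")
    for comp in cell.compartments:
        comp.axial_coupling_to_parent = 0.0
    cell.spike_threshold = 100.0
    cfg = NetworkConfig(cells=[cell], synapses=[], drives=[], duration=200.0,
                        dt=0.1, seed=0, init_perturbation_mv=0.0)
    amp, gl, cm, el = 0.5, 0.1, 1.0, -65.0
    res = trisyn.integrate_network(cfg, step_current={
        "cell_id": "C1", "compartment": 0, "amplitude": amp,
        "t_on": 0.0, "t_off": 200.0})
    tau = cm / gl
    t5 = 5 * tau
    idx = int(round(t5 / cfg.dt))
    expected = el + (amp / gl) * (1 - np.exp(-t5 / tau))
    v = res.voltage_traces["C1"][idx]
    assert abs(v - expected) / abs(amp / gl) < 0.01


def test_determinism_bit_identical():
    cfg = trisyn.build_default_network(seed=1, duration=3000.0)
    r1 = trisyn.integrate_network(cfg)
    r2 = trisyn.integrate_network(trisyn.build_default_network(seed=1, duration=3000.0))
    for cid in r1.spike_times:
        np.testing.assert_array_equal(r1.spike_times[cid], r2.spike_times[cid])
        np.testing.assert_array_equal(r1.voltage_traces[cid], r2.voltage_traces[cid])
    assert r1.final_weights == r2.final_weights


def test_refractoriness(control_result):
    cfg, res = control_result
    refrac = {c.cell_id: c.refractory_period for c in cfg.cells}
    for cid, t in res.spike_times.items():
        if t.size > 1:
            assert np.min(np.diff(t)) >= refrac[cid] - 1e-9


def test_theta_entrainment_of_control(control_result):
    """Principal-cell burst onsets recur at roughly the theta period."""
    from trisyn.spike_metrics import SpikeTrain, segment_bursts

    cfg, res = control_result
    onsets = []
    for cid in trisyn.region_cells(cfg, "DG-CA3-CA1"):
        t = res.spike_times[cid]
        bursts = segment_bursts(SpikeTrain(cid, t, cfg.duration))
        starts = np.array([b[0] for b in bursts])
        if starts.size > 10:
            onsets.append(np.median(np.diff(starts)))
    assert onsets, "control cells must burst"
    med = np.median(onsets)
    assert abs(med - THETA_PERIOD) / THETA_PERIOD < 0.2


# --- LTP -------------------------------------------------------------------

def test_ltp_no_coincidence_is_identity():
    p = LTPParams(learning_rate=0.1, weight_ceiling=2.0, coincidence_window=20.0)
    w = trisyn.apply_ltp([1.0], [[100.0]], [[300.0]], p)
    assert w[0] == 1.0


def test_ltp_at_ceiling_saturates():
    p = LTPParams(learning_rate=0.1, weight_ceiling=2.0, coincidence_window=20.0)
    w = trisyn.apply_ltp([2.0], [[100.0]], [[110.0]], p)
    assert w[0] == 2.0


def test_ltp_k_coincidences_scalar_formula():
    p = LTPParams(learning_rate=0.01, weight_ceiling=2.0, coincidence_window=20.0)
    pre = [10.0, 50.0, 90.0]
    post = [15.0, 60.0, 95.0]  # three coincident pairs
    w0 = 0.5
    w = trisyn.apply_ltp([w0], [pre], [post], p)
    expected = w0 + 3 * 0.01 * (1 - w0 / 2.0)
    assert abs(w[0] - expected) < 1e-12


def test_ltp_rejects_negative_rate():
    with pytest.raises(ValueError):
        trisyn.apply_ltp([1.0], [[1.0]], [[2.0]],
                         LTPParams(learning_rate=-0.1))


@given(st.lists(st.floats(0.0, 1.9), min_size=1, max_size=5))
@settings(deadline=None, max_examples=30)
def test_ltp_monotone_and_bounded(ws):
    p = LTPParams(learning_rate=0.2, weight_ceiling=2.0, coincidence_window=50.0)
    pre = [[10.0, 40.0]] * len(ws)
    post = [[20.0, 60.0]] * len(ws)
    out = trisyn.apply_ltp(ws, pre, post, p)
    assert np.all(out >= np.asarray(ws))
    assert np.all(out <= 2.0)


def test_ltp_weights_grow_during_simulation():
    cfg = trisyn.build_default_network(seed=0, duration=3000.0)
    res = trisyn.integrate_network(cfg)
    plastic = [i for i, s in enumerate(cfg.synapses) if s.plastic]
    final = np.array(res.final_weights)[plastic]
    assert np.all(final >= 1.0)
    assert np.any(final > 1.0)
    assert np.all(final <= cfg.ltp_params.weight_ceiling + 1e-12)
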