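"""Network integration: drives, receptor gating, LTP, and the simulator.

The membrane model is a conductance-based leaky compartment tree with
threshold-reset spiking at the soma.  NMDA receptors carry the standard
voltage-dependent magnesium block; excitatory pathways can potentiate
through a coincidence-gated, potentiation-only Hebbian rule.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernel
from .config import LTPParams, NetworkConfig, SimulationResult

GAMMA_MOD_DEPTH = 0.8  # depth of the gamma carrier modulation


class IntegrationError(RuntimeError):
    """Raised when the membrane state becomes non-finite."""


def nmda_gating(voltage: float | np.ndarray) -> float | np.ndarray:
    """Voltage dependence of the NMDA magnesium block.

    Jahr-Stevens sigmoid ``1 / (1 + [Mg]/3.57 * exp(-0.062 V))`` with
    [Mg2+] = 1 mM.  Monotone in V, -> 0 at strong hyperpolarization and
    -> 1 at strong depolarization.
    """
    v = np.asarray(voltage, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("nmda_gating requires finite voltage")
    out = 1.0 / (1.0 + _kernel.MG_FACTOR * np.exp(-_kernel.MG_SLOPE * v))
    return float(out) if np.isscalar(voltage) or out.ndim == 0 else out


def _theta_envelope(t_ms, freq_hz, phase, sharpness):
    """Normalized theta envelope: mean 1 over a cycle, sharply peaked."""
    x = (0.5 * (1.0 + np.cos(2e-3 * np.pi * freq_hz * t_ms + phase))) ** sharpness
    # normalization: mean of ((1+cos)/2)^s over a cycle = C(2s, s) / 4^s for integer s
    grid = np.linspace(0.0, 2.0 * np.pi, 2048, endpoint=False)
    mean = np.mean((0.5 * (1.0 + np.cos(grid))) ** sharpness)
    return x / mean


def drive_rate(drive, t_ms: np.ndarray) -> np.ndarray:
    """Instantaneous rate (spikes/s) of the theta-nested gamma drive."""
    theta = _theta_envelope(t_ms, drive.theta_frequency, drive.theta_phase_offset, drive.theta_sharpness)
    gamma = 1.0 + GAMMA_MOD_DEPTH * np.cos(2e-3 * np.pi * drive.gamma_frequency * t_ms)
    return drive.mean_rate * theta * gamma


def generate_drive_trains(drive, n_targets: int, duration: float, dt: float) -> list[np.ndarray]:
    """Spike trains (ms) for ``n_targets`` independent fibers of one drive.

    Stochastic drives are inhomogeneous Poisson processes generated by
    thinning; the septal pacemaker (``deterministic=True``) emits
    clock-locked gamma-frequency spikes during the active half of each
    theta cycle, identically across seeds.
    """
    theta_period = 1000.0 / drive.theta_frequency
    if duration < theta_period:
        raise ValueError("duration must cover at least one theta period")
    if drive.deterministic:
        return _pacemaker_trains(drive, n_targets, duration)
    rng = np.random.default_rng(drive.seed)
    # rate ceiling for thinning
    peak = drive.mean_rate * _theta_envelope(
        np.array([-drive.theta_phase_offset * theta_period / (2 * np.pi)]),
        drive.theta_frequency, drive.theta_phase_offset, drive.theta_sharpness,
    )[0] * (1.0 + GAMMA_MOD_DEPTH) * 1.05 + 1e-9
    trains = []
    for _ in range(n_targets):
        n_cand = rng.poisson(peak * duration / 1000.0)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        keep = rng.uniform(0.0, peak, n_cand) < drive_rate(drive, cand)
        trains.append(cand[keep])
    return trains


def _pacemaker_trains(drive, n_targets, duration):
    """Deterministic theta-locked gamma bursts.

    Each fiber emits ``round(mean_rate / theta_frequency)`` spikes per
    theta cycle, paced at the gamma interval and centred on the fiber's
    theta-envelope peak, with a fixed per-fiber stagger so fibers tile
    the active window instead of firing in lockstep.  Identical across
    seeds: the pacemaker is a clock, not a point process.
    """
    theta_period = 1000.0 / drive.theta_frequency
    isi = 1000.0 / drive.gamma_frequency
    per_cycle = int(round(drive.mean_rate / drive.theta_frequency))
    if per_cycle < 1:
        return [np.empty(0) for _ in range(n_targets)]
    # compress the burst into the theta-on window (about a third of the
    # cycle), never slower than the gamma interval
    window = theta_period / 3.0
    if per_cycle > 1:
        isi = min(isi, window / (per_cycle - 1))
    burst_span = (per_cycle - 1) * isi
    n_cycles = int(math.ceil(duration / theta_period))
    offset = -drive.theta_phase_offset * theta_period / (2.0 * np.pi)
    trains = []
    for k in range(n_targets):
        stagger = (k * 2.7) % isi + 0.01 * k  # deterministic fiber stagger
        times = []
        for c in range(-1, n_cycles + 1):
            start = c * theta_period + offset - burst_span / 2.0 + stagger
            for j in range(per_cycle):
                t = start + j * isi
                if 0.0 <= t < duration:
                    times.append(t)
        trains.append(np.array(sorted(times)))
    return trains


def apply_ltp(weights, pre_spike_times, post_spike_times, ltp_params: LTPParams):
    """Batch potentiation-only weight update.

    For each synapse, every (pre, post) spike pair with
    ``0 <= t_post - t_pre <= coincidence_window`` counts as one
    coincidence; the weight moves by
    ``k * learning_rate * (1 - w / weight_ceiling)`` and is clipped at
    the ceiling.  Weights never decrease.
    """
    if ltp_params.learning_rate < 0:
        raise ValueError("learning_rate must be >= 0")
    w = np.asarray(weights, dtype=float).copy()
    win = ltp_params.coincidence_window
    for i in range(len(w)):
        pre = np.asarray(pre_spike_times[i], dtype=float)
        post = np.asarray(post_spike_times[i], dtype=float)
        if pre.size == 0 or post.size == 0:
            continue
        diffs = post[:, None] - pre[None, :]
        k = int(np.count_nonzero((diffs >= 0.0) & (diffs <= win)))
        if k:
            w[i] = min(
                ltp_params.weight_ceiling,
                w[i] + k * ltp_params.learning_rate * (1.0 - w[i] / ltp_params.weight_ceiling),
            )
    return w


def _pack_arrays(config: NetworkConfig):
    """Flatten a NetworkConfig into the kernel's array representation."""
    dt = config.dt
    cells = config.cells
    cell_index = {c.cell_id: i for i, c in enumerate(cells)}

    comp_offset = []
    cm, gl, el, ga, parent = [], [], [], [], []
    soma_idx = []
    off = 0
    for c in cells:
        comp_offset.append(off)
        for j, comp in enumerate(c.compartments):
            cm.append(comp.membrane_capacitance)
            gl.append(comp.leak_conductance)
            el.append(comp.leak_reversal)
            ga.append(comp.axial_coupling_to_parent)
            parent.append(off + comp.parent if comp.parent >= 0 else -1)
            if comp.parent < 0:
                soma_idx.append(off + j)
        off += len(c.compartments)

    syns = config.synapses
    n_syn = len(syns)
    post_comp = np.empty(n_syn, dtype=np.int64)
    erev = np.empty(n_syn)
    gmax_eff = np.empty(n_syn)
    w = np.empty(n_syn)
    dr = np.empty(n_syn)
    dd = np.empty(n_syn)
    norm = np.empty(n_syn)
    delay_steps = np.empty(n_syn, dtype=np.int64)
    is_nmda = np.zeros(n_syn, dtype=np.bool_)
    plastic = np.zeros(n_syn, dtype=np.bool_)
    pre_cell = np.full(n_syn, -1, dtype=np.int64)
    for s, syn in enumerate(syns):
        post_comp[s] = comp_offset[cell_index[syn.post_cell_id]] + syn.post_compartment_index
        erev[s] = syn.reversal
        gmax_eff[s] = syn.max_conductance if syn.active else 0.0
        w[s] = syn.weight
        dr[s] = math.exp(-dt / syn.rise_time)
        dd[s] = math.exp(-dt / syn.decay_time)
        tp = math.log(syn.decay_time / syn.rise_time) * syn.rise_time * syn.decay_time / (
            syn.decay_time - syn.rise_time
        )
        norm[s] = 1.0 / (math.exp(-tp / syn.decay_time) - math.exp(-tp / syn.rise_time))
        delay_steps[s] = max(0, int(round(syn.delay / dt)))
        is_nmda[s] = syn.receptor == "NMDA"
        plastic[s] = syn.plastic
        if syn.pre_cell_id in cell_index:
            pre_cell[s] = cell_index[syn.pre_cell_id]

    n_cells = len(cells)
    out_lists = [[] for _ in range(n_cells)]
    in_lists = [[] for _ in range(n_cells)]
    for s, syn in enumerate(syns):
        if pre_cell[s] >= 0:
            out_lists[pre_cell[s]].append(s)
        if plastic[s]:
            in_lists[cell_index[syn.post_cell_id]].append(s)

    def _csr(lists):
        start = np.zeros(n_cells + 1, dtype=np.int64)
        flat = []
        for i, lst in enumerate(lists):
            flat.extend(lst)
            start[i + 1] = len(flat)
        return start, np.array(flat, dtype=np.int64)

    out_start, out_syn = _csr(out_lists)
    in_start, in_syn = _csr(in_lists)

    arrays = dict(
        cm=np.array(cm), gl=np.array(gl), el=np.array(el), ga=np.array(ga),
        parent=np.array(parent, dtype=np.int64),
        soma_idx=np.array(soma_idx, dtype=np.int64),
        thresh=np.array([c.spike_threshold for c in cells]),
        vreset=np.array([c.reset_potential for c in cells]),
        refrac_steps=np.array(
            [max(1, int(round(c.refractory_period / dt))) for c in cells], dtype=np.int64
        ),
        post_comp=post_comp, erev=erev, gmax_eff=gmax_eff, w=w,
        dr=dr, dd=dd, norm=norm, delay_steps=delay_steps,
        is_nmda=is_nmda, plastic=plastic, pre_cell=pre_cell,
        out_start=out_start, out_syn=out_syn, in_start=in_start, in_syn=in_syn,
    )
    return arrays, cell_index


def _external_events(config: NetworkConfig, cell_index):
    """Precompute (arrival step, synapse index) for all drive spikes."""
    dt = config.dt
    n_steps = int(round(config.duration / dt))
    # group synapses by external fiber id
    fiber_syns: dict[str, list[int]] = {}
    for s, syn in enumerate(config.synapses):
        if syn.pre_cell_id not in cell_index:
            fiber_syns.setdefault(syn.pre_cell_id, []).append(s)
    steps, syn_ids = [], []
    for drive in config.drives:
        trains = generate_drive_trains(drive, drive.n_fibers, config.duration, dt)
        for k, train in enumerate(trains):
            fid = f"{drive.source}:{k}"
            targets = fiber_syns.get(fid, [])
            if not targets:
                continue
            for s in targets:
                delay = config.synapses[s].delay
                arr = np.round((train + delay) / dt).astype(np.int64)
                arr = arr[(arr >= 0) & (arr < n_steps)]
                steps.append(arr)
                syn_ids.append(np.full(arr.size, s, dtype=np.int64))
    if steps:
        steps = np.concatenate(steps)
        syn_ids = np.concatenate(syn_ids)
        order = np.argsort(steps, kind="stable")
        return steps[order], syn_ids[order]
    return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)


def integrate_network(config: NetworkConfig,
                      step_current: dict | None = None) -> SimulationResult:
    """Integrate the network and return traces, spikes and final weights.

    Deterministic: the same config (including seed) yields bit-identical
    results.  Raises :class:`IntegrationError` if the state blows up,
    naming the cell, compartment and time of the failure.

    ``step_current`` optionally injects a constant current step:
    ``{"cell_id": ..., "compartment": idx, "amplitude": µA/cm²,
    "t_on": ms, "t_off": ms}``.
    """
    config.validate()
    arrays, cell_index = _pack_arrays(config)
    ext_step, ext_syn = _external_events(config, cell_index)
    n_steps = int(round(config.duration / config.dt))
    n_cells = len(config.cells)

    # seed-dependent initial condition: small hyperpolarizing offsets
    rng = np.random.default_rng(config.seed)
    v0 = arrays["el"] + rng.uniform(-config.init_perturbation_mv, 0.0,
                                    arrays["el"].shape)
    vtr = np.empty((n_cells, n_steps))
    cap = max(1000, int(n_cells * config.duration))  # ~1 kHz per cell headroom
    spike_cell = np.empty(cap, dtype=np.int64)
    spike_step = np.empty(cap, dtype=np.int64)

    iext = np.zeros_like(v0)
    i_on, i_off = 0, -1
    if step_current:
        cidx = [c.cell_id for c in config.cells].index(step_current["cell_id"])
        off = sum(len(c.compartments) for c in config.cells[:cidx])
        iext[off + step_current.get("compartment", 0)] = step_current["amplitude"]
        i_on = int(round(step_current["t_on"] / config.dt))
        i_off = int(round(step_current["t_off"] / config.dt))

    n_spikes, bad_comp, bad_step = _kernel.run_network(
        n_steps, config.dt, v0,
        arrays["cm"], arrays["gl"], arrays["el"], arrays["ga"], arrays["parent"],
        arrays["soma_idx"], arrays["thresh"], arrays["vreset"], arrays["refrac_steps"],
        arrays["post_comp"], arrays["erev"], arrays["gmax_eff"], arrays["w"],
        arrays["dr"], arrays["dd"], arrays["norm"], arrays["delay_steps"],
        arrays["is_nmda"], arrays["plastic"], arrays["pre_cell"],
        arrays["out_start"], arrays["out_syn"], arrays["in_start"], arrays["in_syn"],
        ext_step, ext_syn,
        iext, i_on, i_off,
        config.ltp_params.learning_rate, config.ltp_params.weight_ceiling,
        max(1, int(round(config.ltp_params.coincidence_window / config.dt))),
        vtr, spike_cell, spike_step,
    )
    if bad_comp >= 0:
        # locate offending cell
        off = 0
        for c in config.cells:
            if off <= bad_comp < off + len(c.compartments):
                raise IntegrationError(
                    f"non-finite state in cell {c.cell_id} compartment "
                    f"{bad_comp - off} at t = {bad_step * config.dt:.1f} ms"
                )
            off += len(c.compartments)
        raise IntegrationError(f"non-finite state at t = {bad_step * config.dt:.1f} ms")

    ids = [c.cell_id for c in config.cells]
    spikes: dict[str, np.ndarray] = {cid: [] for cid in ids}
    for i in range(n_spikes):
        spikes[ids[spike_cell[i]]].append(spike_step[i] * config.dt)
    spike_times = {cid: np.array(ts) for cid, ts in spikes.items()}
    traces = {cid: vtr[i] for i, cid in enumerate(ids)}
    return SimulationResult(
        voltage_traces=traces,
        spike_times=spike_times,
        final_weights=list(arrays["w"]),
        config_echo=config,
        time=np.arange(n_steps) * config.dt,
    )
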