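"""Numba inner loop for the compartmental network integrator.

State per compartment: membrane potential V (mV).  Each synapse carries a
rise/decay exponential pair; arriving spikes increment both by one unit
and the conductance is ``gmax * w * norm * (decay - rise)`` so its peak
equals ``gmax * w``.  Membrane update is exponential Euler on the
instantaneous total conductance; axial currents use the neighbours'
previous-step voltages.
"""

import numpy as np
from numba import njit

MG_FACTOR = 1.0 / 3.57  # [Mg2+] = 1 mM over the Jahr-Stevens constant
MG_SLOPE = 0.062  # 1/mV


@njit(cache=True)
def nmda_gate_scalar(v):
    return 1.0 / (1.0 + MG_FACTOR * np.exp(-MG_SLOPE * v))


@njit(cache=True)
def run_network(
    n_steps,
    dt,
    # compartments
    v,            # (n_comp,) initial voltages, modified in place
    cm, gl, el, ga, parent,
    # cells
    soma_idx, thresh, vreset, refrac_steps,
    # synapses
    post_comp, erev, gmax_eff, w, dr, dd, norm, delay_steps,
    is_nmda, plastic, pre_cell,
    # grouping: outgoing synapses per cell / incoming plastic synapses per cell
    out_start, out_syn, in_start, in_syn,
    # external events (arrival steps, already delayed, sorted)
    ext_step, ext_syn,
    # step-current injection (µA/cm² per compartment, active on [i_on, i_off))
    iext, i_on, i_off,
    # plasticity
    lr, ceiling, win_steps,
    # outputs
    vtr,          # (n_cells, n_steps)
    spike_cell, spike_step,
):
    n_comp = v.shape[0]
    n_cells = soma_idx.shape[0]
    n_syn = post_comp.shape[0]

    gr = np.zeros(n_syn)
    gd = np.zeros(n_syn)
    last_pre = np.full(n_syn, -2_000_000_000, dtype=np.int64)
    last_spike = np.full(n_cells, -2_000_000_000, dtype=np.int64)

    ring = 1
    for s in range(n_syn):
        if delay_steps[s] + 1 > ring:
            ring = delay_steps[s] + 1
    pend = np.zeros((ring, n_syn))

    G = np.empty(n_comp)
    A = np.empty(n_comp)

    ep = 0
    n_ext = ext_step.shape[0]
    n_spikes = 0
    max_spikes = spike_cell.shape[0]

    for step in range(n_steps):
        # 1. deliver pending network spikes and external events
        row = step % ring
        for s in range(n_syn):
            p = pend[row, s]
            if p > 0.0:
                gr[s] += p
                gd[s] += p
                last_pre[s] = step
                pend[row, s] = 0.0
        while ep < n_ext and ext_step[ep] == step:
            s = ext_syn[ep]
            gr[s] += 1.0
            gd[s] += 1.0
            last_pre[s] = step
            ep += 1

        # 2. kinetic decay
        for s in range(n_syn):
            gr[s] *= dr[s]
            gd[s] *= dd[s]

        # 3. synaptic conductances -> per-compartment totals
        inject = i_on <= step < i_off
        for i in range(n_comp):
            G[i] = gl[i]
            A[i] = gl[i] * el[i]
            if inject:
                A[i] += iext[i]
        for s in range(n_syn):
            gm = gmax_eff[s]
            if gm == 0.0:
                continue
            g = gm * w[s] * norm[s] * (gd[s] - gr[s])
            if g <= 0.0:
                continue
            pc = post_comp[s]
            if is_nmda[s]:
                g *= nmda_gate_scalar(v[pc])
            G[pc] += g
            A[pc] += g * erev[s]

        # 4. axial coupling (explicit in neighbour voltages)
        for i in range(n_comp):
            p = parent[i]
            if p >= 0:
                G[i] += ga[i]
                A[i] += ga[i] * v[p]
                G[p] += ga[i]
                A[p] += ga[i] * v[i]

        # 5. exponential Euler membrane update
        for i in range(n_comp):
            vinf = A[i] / G[i]
            v[i] = vinf + (v[i] - vinf) * np.exp(-dt * G[i] / cm[i])

        # 6. spike detection, reset, refractory clamp, LTP, event scheduling
        for c in range(n_cells):
            sc = soma_idx[c]
            if step - last_spike[c] < refrac_steps[c]:
                v[sc] = vreset[c]
                vtr[c, step] = v[sc]
                continue
            if v[sc] >= thresh[c]:
                if n_spikes < max_spikes:
                    spike_cell[n_spikes] = c
                    spike_step[n_spikes] = step
                    n_spikes += 1
                last_spike[c] = step
                vtr[c, step] = 30.0
                v[sc] = vreset[c]
                # potentiate coincident plastic inputs of this cell
                for k in range(in_start[c], in_start[c + 1]):
                    s = in_syn[k]
                    if step - last_pre[s] <= win_steps:
                        nw = w[s] + lr * (1.0 - w[s] / ceiling)
                        # snap once the soft bound is effectively reached, so
                        # saturated weights stop drifting asymptotically
                        if nw >= ceiling - 1e-6 * ceiling:
                            nw = ceiling
                        w[s] = nw
                # schedule outgoing synaptic events
                for k in range(out_start[c], out_start[c + 1]):
                    s = out_syn[k]
                    pend[(step + delay_steps[s]) % ring, s] += 1.0
            else:
                vtr[c, step] = v[sc]

        # 7. blow-up guard
        if step % 200 == 0:
            for i in range(n_comp):
                if not np.isfinite(v[i]):
                    return n_spikes, i, step
    for i in range(n_comp):
        if not np.isfinite(v[i]):
            return n_spikes, i, n_steps - 1
    return n_spikes, -1, -1
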