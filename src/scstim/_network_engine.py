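"""Numba core for the dorsal-horn network: per-neuron 4-compartment
Crank–Nicolson cables, double-exponential synapses driven by afferent spike
schedules and by internally detected soma spikes (1 ms conduction delay).

Units: mV, ms, nF, µS, nA; Ca pool in µM.
"""

import numba
import numpy as np

from scstim import dh_network as net

__all__ = ["build_engine_arrays", "run_network"]

N_NEURONS = 9
N_COMP = 4


@numba.njit(cache=True)
def _gates_steady(v):
    am = 0.32 * (v + 54.0) / (1.0 - np.exp(-(v + 54.0) / 4.0))
    bm = 0.28 * (v + 27.0) / (np.exp((v + 27.0) / 5.0) - 1.0)
    ah = 0.128 * np.exp(-(v + 50.0) / 18.0)
    bh = 4.0 / (1.0 + np.exp(-(v + 27.0) / 5.0))
    an = 0.032 * (v + 52.0) / (1.0 - np.exp(-(v + 52.0) / 5.0))
    bn = 0.5 * np.exp(-(v + 57.0) / 40.0)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


@numba.njit(cache=True)
def run_network_core(
    dt,
    n_steps,
    cm,
    gl,
    gna,
    gkdr,
    ga_,
    gca,
    gcan,
    gax,
    s_tgt,
    s_e,
    s_g,
    s_d1,
    s_d2,
    s_nmda,
    s_A0,
    s_B0,
    aff_steps,
    aff_syn,
    ic_src,
    ic_syn,
    delay_steps,
    record_v,
):
    v = np.full(N_NEURONS * N_COMP, net.E_LEAK)
    m = np.empty(N_NEURONS * N_COMP)
    h = np.empty(N_NEURONS * N_COMP)
    nn = np.empty(N_NEURONS * N_COMP)
    aa = np.empty(N_NEURONS * N_COMP)
    bb = np.empty(N_NEURONS * N_COMP)
    qq = np.empty(N_NEURONS * N_COMP)
    ca = np.full(N_NEURONS * N_COMP, 0.05)
    zz = np.zeros(N_NEURONS * N_COMP)
    m0, h0, n0 = _gates_steady(net.E_LEAK)
    for j in range(N_NEURONS * N_COMP):
        m[j] = m0
        h[j] = h0
        nn[j] = n0
        aa[j] = 1.0 / (1.0 + np.exp(-(net.E_LEAK + 50.0) / 20.0))
        bb[j] = 1.0 / (1.0 + np.exp((net.E_LEAK + 80.0) / 6.0))
        qq[j] = 1.0 / (1.0 + np.exp(-(net.E_LEAK + 30.0) / 5.0))

    n_syn = s_tgt.shape[0]
    # warm start: stationary mean of each double-exponential state under
    # its slot's baseline spike rate (removes slow-receptor equilibration
    # transients, NK1 in particular)
    A = s_A0.copy()
    B = s_B0.copy()
    n_conn = ic_src.shape[0]
    pending = np.full(n_conn, -1, dtype=np.int64)

    syn_G = np.zeros(N_NEURONS * N_COMP)
    syn_GE = np.zeros(N_NEURONS * N_COMP)

    max_spikes = int(n_steps * dt / net.SOMA_SPIKE_LOCKOUT_MS) + 8
    spikes = np.zeros((N_NEURONS, max_spikes))
    counts = np.zeros(N_NEURONS, dtype=np.int64)
    last_spike = np.full(N_NEURONS, -1e9)
    v_prev_soma = np.full(N_NEURONS, net.E_LEAK)
    diverged = np.zeros(N_NEURONS, dtype=np.bool_)

    if record_v:
        v_rec = np.empty((N_NEURONS, n_steps))
    else:
        v_rec = np.empty((N_NEURONS, 1))

    aff_ptr = 0
    n_aff = aff_steps.shape[0]

    lo = np.empty(N_COMP)
    di = np.empty(N_COMP)
    up = np.empty(N_COMP)
    rr = np.empty(N_COMP)

    for it in range(n_steps):
        t = it * dt
        # synapse state decay, then scheduled impulses
        for s in range(n_syn):
            A[s] *= s_d1[s]
            B[s] *= s_d2[s]
        while aff_ptr < n_aff and aff_steps[aff_ptr] == it:
            s = aff_syn[aff_ptr]
            A[s] += 1.0
            B[s] += 1.0
            aff_ptr += 1
        for c in range(n_conn):
            if pending[c] == it:
                A[ic_syn[c]] += 1.0
                B[ic_syn[c]] += 1.0
                pending[c] = -1

        # synaptic conductance accumulation
        for j in range(N_NEURONS * N_COMP):
            syn_G[j] = 0.0
            syn_GE[j] = 0.0
        for s in range(n_syn):
            g = s_g[s] * (B[s] - A[s])
            if g <= 0.0:
                continue
            j = s_tgt[s]
            if s_nmda[s]:
                g *= 1.0 / (1.0 + np.exp(-(v[j] - net.NMDA_HALF_BLOCK_MV) / net.NMDA_SLOPE_MV))
            syn_G[j] += g
            syn_GE[j] += g * s_e[s]

        # per-neuron integration
        for nrn in range(N_NEURONS):
            base = nrn * N_COMP
            for k in range(N_COMP):
                j = base + k
                vj = v[j]
                # HH gates (Rush–Larsen)
                if gna[j] > 0.0:
                    x = vj + 54.0
                    am = 0.32 * x / (1.0 - np.exp(-x / 4.0)) if abs(x) > 1e-9 else 0.32 * 4.0
                    x = vj + 27.0
                    bm = 0.28 * x / (np.exp(x / 5.0) - 1.0) if abs(x) > 1e-9 else 0.28 * 5.0
                    ah = 0.128 * np.exp(-(vj + 50.0) / 18.0)
                    bh = 4.0 / (1.0 + np.exp(-(vj + 27.0) / 5.0))
                    x = vj + 52.0
                    an = 0.032 * x / (1.0 - np.exp(-x / 5.0)) if abs(x) > 1e-9 else 0.032 * 5.0
                    bn = 0.5 * np.exp(-(vj + 57.0) / 40.0)
                    tm = 1.0 / (am + bm)
                    th = 1.0 / (ah + bh)
                    tn = 1.0 / (an + bn)
                    m[j] = am * tm + (m[j] - am * tm) * np.exp(-dt / tm)
                    h[j] = ah * th + (h[j] - ah * th) * np.exp(-dt / th)
                    nn[j] = an * tn + (nn[j] - an * tn) * np.exp(-dt / tn)
                if ga_[j] > 0.0:
                    ai = 1.0 / (1.0 + np.exp(-(vj + 50.0) / 20.0))
                    bi = 1.0 / (1.0 + np.exp((vj + 80.0) / 6.0))
                    aa[j] = ai + (aa[j] - ai) * np.exp(-dt / 5.0)
                    bb[j] = bi + (bb[j] - bi) * np.exp(-dt / 150.0)
                if gca[j] > 0.0:
                    qi = 1.0 / (1.0 + np.exp(-(vj + 30.0) / 5.0))
                    qq[j] = qi + (qq[j] - qi) * np.exp(-dt / 40.0)
                    ica = gca[j] * qq[j] * qq[j] * (vj - net.E_CA)
                    ca[j] += dt * (-0.01 * ica - (ca[j] - 0.05) / 250.0)
                    if ca[j] < 0.0:
                        ca[j] = 0.0
                if gcan[j] > 0.0:
                    c2 = ca[j] * ca[j]
                    zi = c2 / (c2 + 0.25)
                    zz[j] = zi + (zz[j] - zi) * np.exp(-dt / 150.0)

            # assemble tridiagonal CN system
            for k in range(N_COMP):
                j = base + k
                G = gl[j] + syn_G[j]
                GE = gl[j] * net.E_LEAK + syn_GE[j]
                if gna[j] > 0.0:
                    g1 = gna[j] * m[j] ** 3 * h[j]
                    g2 = gkdr[j] * nn[j] ** 4
                    G += g1 + g2
                    GE += g1 * net.E_NA + g2 * net.E_K
                if ga_[j] > 0.0:
                    g3 = ga_[j] * aa[j] * bb[j]
                    G += g3
                    GE += g3 * net.E_K
                if gca[j] > 0.0:
                    g4 = gca[j] * qq[j] * qq[j]
                    G += g4
                    GE += g4 * net.E_CA
                if gcan[j] > 0.0:
                    g5 = gcan[j] * zz[j]
                    G += g5
                    GE += g5 * net.E_CAN
                g_left = gax[nrn, k - 1] if k > 0 else 0.0
                g_right = gax[nrn, k] if k < N_COMP - 1 else 0.0
                flux = 0.0
                if k > 0:
                    flux += g_left * (v[j - 1] - v[j])
                if k < N_COMP - 1:
                    flux += g_right * (v[j + 1] - v[j])
                di[k] = cm[j] / dt + G / 2.0 + (g_left + g_right) / 2.0
                lo[k] = -g_left / 2.0
                up[k] = -g_right / 2.0
                rr[k] = cm[j] / dt * v[j] - G / 2.0 * v[j] + GE + flux / 2.0

            # Thomas solve
            for k in range(1, N_COMP):
                w = lo[k] / di[k - 1]
                di[k] -= w * up[k - 1]
                rr[k] -= w * rr[k - 1]
            xk = rr[N_COMP - 1] / di[N_COMP - 1]
            v[base + N_COMP - 1] = xk
            for k in range(N_COMP - 2, -1, -1):
                xk = (rr[k] - up[k] * v[base + k + 1]) / di[k]
                v[base + k] = xk

            vs = v[base + net.SOMA]
            if record_v:
                v_rec[nrn, it] = vs
            if np.isnan(vs) or vs > 200.0 or vs < -200.0:
                diverged[nrn] = True
            if (
                vs >= net.SOMA_SPIKE_THRESHOLD_MV
                and v_prev_soma[nrn] < net.SOMA_SPIKE_THRESHOLD_MV
                and (t - last_spike[nrn]) >= net.SOMA_SPIKE_LOCKOUT_MS
            ):
                if counts[nrn] < max_spikes:
                    spikes[nrn, counts[nrn]] = t
                    counts[nrn] += 1
                last_spike[nrn] = t
                for c in range(n_conn):
                    if ic_src[c] == nrn:
                        pending[c] = it + delay_steps
            v_prev_soma[nrn] = vs

    return spikes, counts, v_rec, diverged


def build_engine_arrays(network, slot_trains, duration_ms, baseline_ms=None):
    """Flatten a NetworkModel plus slot spike trains into engine arrays.

    ``baseline_ms`` bounds the window used to estimate each afferent
    slot's baseline rate for the warm start of its synapse states
    (defaults to the full duration).
    """
    dt = network.dt_ms
    n_steps = int(round(duration_ms / dt))
    if baseline_ms is None:
        baseline_ms = duration_ms

    cm = np.zeros(N_NEURONS * N_COMP)
    gl = np.zeros(N_NEURONS * N_COMP)
    gna = np.zeros(N_NEURONS * N_COMP)
    gkdr = np.zeros(N_NEURONS * N_COMP)
    ga_ = np.zeros(N_NEURONS * N_COMP)
    gca = np.zeros(N_NEURONS * N_COMP)
    gcan = np.zeros(N_NEURONS * N_COMP)
    gax = np.zeros((N_NEURONS, N_COMP - 1))
    neuron_keys = []
    for node in range(3):
        for ci, cls in enumerate(net.NEURON_CLASSES):
            nrn = node * 3 + ci
            neuron_keys.append((node, cls))
            spec = network.neurons[nrn]
            areas = net._compartment_areas_um2(spec.geometry)
            to_nF = areas * 1e-5
            to_uS = areas * 1e-2  # S/cm² -> µS
            for k in range(N_COMP):
                j = nrn * N_COMP + k
                cm[j] = net.CM * to_nF[k]
                gl[j] = net.G_LEAK * to_uS[k]
                if k != net.DENDRITE:  # active conductances off the dendrite
                    gna[j] = spec.channels["g_na"] * to_uS[k]
                    gkdr[j] = spec.channels["g_kdr"] * to_uS[k]
                if k == net.SOMA:
                    ga_[j] = spec.channels["g_a"] * to_uS[k]
                    gca[j] = spec.channels["g_ca"] * to_uS[k]
                    gcan[j] = spec.channels["g_can"] * to_uS[k]
            gax[nrn] = net._axial_g_uS(spec.geometry, net.RHO_AXIAL[cls])

    # --- synapses: afferent first, then internal -----------------------------
    s_tgt, s_e, s_g, s_d1, s_d2, s_nmda = [], [], [], [], [], []
    s_A0, s_B0 = [], []
    impulses = []  # (step, syn_idx)

    slot_counter: dict = {}
    for syn in network.afferent_synapses:
        key = (syn.source, syn.target, syn.receptor, syn.source_node)
        slot = slot_counter.get(key, 0)
        slot_counter[key] = slot + 1
        idx = len(s_tgt)
        tgt_nrn = network.neuron_index(syn.target_node, syn.target)
        s_tgt.append(tgt_nrn * N_COMP + net._TARGET_COMP[syn.receptor])
        s_e.append(syn.e_syn_mV)
        s_g.append(syn.g_max_nS * 1e-3 * net._double_exp_norm(syn.tau1_ms, syn.tau2_ms))
        s_d1.append(np.exp(-dt / syn.tau1_ms))
        s_d2.append(np.exp(-dt / syn.tau2_ms))
        s_nmda.append(syn.receptor == "NMDA")
        train = np.asarray(slot_trains[syn.source][syn.source_node][slot], dtype=float)
        rate_per_ms = np.sum(train < baseline_ms) / baseline_ms if baseline_ms > 0 else 0.0
        s_A0.append(rate_per_ms * syn.tau1_ms)
        s_B0.append(rate_per_ms * syn.tau2_ms)
        for t_ms in train:
            step = int(round(t_ms / dt))
            if 0 <= step < n_steps:
                impulses.append((step, idx))

    ic_src, ic_syn = [], []
    for syn in network.synapses:
        idx = len(s_tgt)
        tgt_nrn = network.neuron_index(syn.target_node, syn.target)
        s_tgt.append(tgt_nrn * N_COMP + net._TARGET_COMP[syn.receptor])
        s_e.append(syn.e_syn_mV)
        s_g.append(syn.g_max_nS * 1e-3 * net._double_exp_norm(syn.tau1_ms, syn.tau2_ms))
        s_d1.append(np.exp(-dt / syn.tau1_ms))
        s_d2.append(np.exp(-dt / syn.tau2_ms))
        s_nmda.append(syn.receptor == "NMDA")
        s_A0.append(0.0)  # internal synapses have fast kinetics: cold start
        s_B0.append(0.0)
        ic_src.append(network.neuron_index(syn.source_node, syn.source))
        ic_syn.append(idx)

    impulses.sort()
    aff_steps = np.array([i[0] for i in impulses], dtype=np.int64)
    aff_syn = np.array([i[1] for i in impulses], dtype=np.int64)

    args = (
        dt,
        n_steps,
        cm,
        gl,
        gna,
        gkdr,
        ga_,
        gca,
        gcan,
        gax,
        np.array(s_tgt, dtype=np.int64),
        np.array(s_e),
        np.array(s_g),
        np.array(s_d1),
        np.array(s_d2),
        np.array(s_nmda, dtype=np.bool_),
        np.array(s_A0),
        np.array(s_B0),
        aff_steps,
        aff_syn,
        np.array(ic_src, dtype=np.int64),
        np.array(ic_syn, dtype=np.int64),
        int(round(net.SYNAPTIC_DELAY_MS / dt)),
    )
    return {"args": args, "neuron_keys": neuron_keys}


def run_network(*args):
    """Run the core and unpack per-neuron spike trains."""
    *core_args, record_v = args
    spikes, counts, v_rec, diverged = run_network_core(*core_args, record_v)
    spike_list = [spikes[i, : counts[i]].copy() for i in range(N_NEURONS)]
    return spike_list, v_rec, diverged
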