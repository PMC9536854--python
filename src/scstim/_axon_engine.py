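"""Numba core for the double-cable axon: Crank–Nicolson voltage solve with
staggered Rush–Larsen gate updates.

State per compartment j: the transaxolemmal voltage v_j and the periaxonal
potential u_j (relative to the grounded far field).  The applied
extracellular potential Ve_j(t) enters through the myelin sheath, which
couples u_j to Ve_j; at nodes the "myelin" conductance is made very large so
u tracks Ve.  The two Kirchhoff equations per compartment form a block
tridiagonal system with 2×2 blocks, solved by block Thomas elimination.

Units: mV, ms, nF, µS, nA.
"""

import numba
import numpy as np

from scstim import mrg

__all__ = ["run_axon"]


@numba.njit(cache=True)
def _gate_rates(v, rates):
    """MRG nodal gate rates at voltage v -> [am, bm, ah, bh, ap, bp, as_, bs]."""
    # fast Na activation
    x = v + 20.4
    rates[0] = 6.57 * x / (1.0 - np.exp(-x / 10.3)) if abs(x) > 1e-9 else 6.57 * 10.3
    x = -(v + 25.7)
    rates[1] = 0.304 * x / (1.0 - np.exp(-x / 9.16)) if abs(x) > 1e-9 else 0.304 * 9.16
    # fast Na inactivation
    x = -(v + 114.0)
    rates[2] = 0.34 * x / (1.0 - np.exp(-x / 11.0)) if abs(x) > 1e-9 else 0.34 * 11.0
    rates[3] = 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    # persistent Na
    x = v + 27.0
    rates[4] = 0.0353 * x / (1.0 - np.exp(-x / 10.2)) if abs(x) > 1e-9 else 0.0353 * 10.2
    x = -(v + 34.0)
    rates[5] = 0.000883 * x / (1.0 - np.exp(-x / 10.0)) if abs(x) > 1e-9 else 0.000883 * 10.0
    # slow K
    rates[6] = 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    rates[7] = 0.03 / (1.0 + np.exp(-(v + 90.0) / 1.0))


@numba.njit(cache=True)
def _steady_gates(v):
    r = np.empty(8)
    _gate_rates(v, r)
    out = np.empty(4)
    for g in range(4):
        a = r[2 * g]
        b = r[2 * g + 1]
        out[g] = a / (a + b)
    return out


@numba.njit(cache=True, fastmath=True)
def run_axon(
    kind,
    cm,
    g_pas,
    e_pas,
    cmy,
    gmy,
    g_ax,
    g_pe,
    node_idx,
    g_naf,
    g_nap,
    g_ks,
    g_l,
    phi_unit,
    drive,
    dt,
    v_rest,
    record_node,
    spike_thresh,
    lockout_ms,
):
    """Integrate the axon under extracellular drive.

    phi_unit : (n,) extracellular potential per µA of drive at each compartment (mV/µA)
    drive : (nt,) drive current in µA (positive = cathodic phase of the pulse)
    Returns (spike_times_ms, v_record, diverged_flag).
    """
    n = kind.shape[0]
    nt = drive.shape[0]
    n_nodes = node_idx.shape[0]

    v = np.full(n, v_rest)
    u = np.zeros(n)
    # nodal gates m, h, p, s
    gates = np.empty((n_nodes, 4))
    g0 = _steady_gates(v_rest)
    for i in range(n_nodes):
        for g in range(4):
            gates[i, g] = g0[g]

    # block tridiagonal workspace (2x2 blocks)
    Dm = np.empty((n, 2, 2))
    cp = np.empty((n, 2, 2))
    dp = np.empty((n, 2))

    Gion = np.zeros(n)
    GEion = np.zeros(n)
    for j in range(n):
        if kind[j] != 0:
            Gion[j] = g_pas[j]
            GEion[j] = g_pas[j] * e_pas

    # Tabulated gate kinetics: steady state and per-step decay factor on a
    # fine voltage grid (removes all exp() calls from the hot loop)
    v_lo = -160.0
    v_hi = 80.0
    dv = 0.05
    n_tab = int((v_hi - v_lo) / dv) + 1
    tab_inf = np.empty((4, n_tab))
    tab_pf = np.empty((4, n_tab))
    tr = np.empty(8)
    for i in range(n_tab):
        vv = v_lo + i * dv
        _gate_rates(vv, tr)
        for g in range(4):
            a = tr[2 * g]
            b = tr[2 * g + 1]
            tau = 1.0 / (a + b)
            tab_inf[g, i] = a * tau
            tab_pf[g, i] = np.exp(-dt / tau)

    spike_times = np.empty(100000)
    n_spikes = 0
    last_spike = -1e9
    v_prev_rec = v[record_node]
    v_rec = np.empty(nt)
    diverged = False
    steps_since_drive = 1000000

    # Ve_j(t) = phi_unit[j] * drive(t): precompute the myelin couplings to
    # the applied field so the time loop only uses scalar drive factors
    cmyphi = cmy * phi_unit
    gmyphi = gmy * phi_unit

    # time-invariant matrix blocks
    d00_const = np.empty(n)
    for j in range(n):
        ga_l = g_ax[j - 1] if j > 0 else 0.0
        ga_r = g_ax[j] if j < n - 1 else 0.0
        gp_l = g_pe[j - 1] if j > 0 else 0.0
        gp_r = g_pe[j] if j < n - 1 else 0.0
        sum_a = ga_l + ga_r
        sum_b = gp_l + gp_r
        d00_const[j] = cm[j] / dt + sum_a / 2.0
        Dm[j, 0, 1] = sum_a / 2.0
        Dm[j, 1, 0] = -sum_a / 2.0
        Dm[j, 1, 1] = -(sum_a + sum_b) / 2.0 - cmy[j] / dt - gmy[j] / 2.0

    for it in range(1, nt):
        s_old = drive[it - 1]
        s_new = drive[it]
        ds_dt = (s_new - s_old) / dt
        s_mid = (s_new + s_old) / 2.0
        t = it * dt

        # staggered gate update (Rush–Larsen) using current nodal voltages
        for i in range(n_nodes):
            j = node_idx[i]
            vj = v[j]
            if vj < v_lo:
                vj = v_lo
            elif vj > v_hi:
                vj = v_hi
            x = (vj - v_lo) / dv
            i0 = int(x)
            if i0 >= n_tab - 1:
                i0 = n_tab - 2
            frac = x - i0
            for g in range(4):
                inf = tab_inf[g, i0] * (1.0 - frac) + tab_inf[g, i0 + 1] * frac
                pf = tab_pf[g, i0] * (1.0 - frac) + tab_pf[g, i0 + 1] * frac
                gates[i, g] = inf + (gates[i, g] - inf) * pf
            m = gates[i, 0]
            h = gates[i, 1]
            p = gates[i, 2]
            s = gates[i, 3]
            gna = g_naf[i] * m * m * m * h
            gnap = g_nap[i] * p * p * p
            gk = g_ks[i] * s
            Gion[j] = gna + gnap + gk + g_l[i]
            GEion[j] = (gna + gnap) * mrg.E_NA + gk * mrg.E_K + g_l[i] * mrg.E_L

        # fused assembly + block-Thomas forward elimination: one sweep over
        # compartments with scalar temporaries (the off-diagonal blocks are
        # simple functions of the constant axial conductances)
        pc00 = pc01 = pc10 = pc11 = 0.0
        pd0 = pd1 = 0.0
        for j in range(n):
            ga_l = g_ax[j - 1] if j > 0 else 0.0
            ga_r = g_ax[j] if j < n - 1 else 0.0
            gp_l = g_pe[j - 1] if j > 0 else 0.0
            gp_r = g_pe[j] if j < n - 1 else 0.0

            vj = v[j]
            uj = u[j]
            phi_j = vj + uj
            ax_flux = 0.0  # sum_k a(phi_k - phi_j)
            pe_flux = 0.0
            if j > 0:
                ax_flux += ga_l * ((v[j - 1] + u[j - 1]) - phi_j)
                pe_flux += gp_l * (u[j - 1] - uj)
            if j < n - 1:
                ax_flux += ga_r * ((v[j + 1] + u[j + 1]) - phi_j)
                pe_flux += gp_r * (u[j + 1] - uj)

            gj = Gion[j]
            a00 = d00_const[j] + gj * 0.5
            a01 = Dm[j, 0, 1]
            a10 = Dm[j, 1, 0]
            a11 = Dm[j, 1, 1]
            r0 = cm[j] / dt * vj - gj * 0.5 * vj + GEion[j] + ax_flux * 0.5
            r1 = (
                -ax_flux * 0.5
                - pe_flux * 0.5
                - cmy[j] / dt * uj
                - cmyphi[j] * ds_dt
                - gmyphi[j] * s_mid
                + gmy[j] * 0.5 * uj
            )
            if j > 0:
                # Lo = [[-l0, -l0], [l0, l1]] with l0 = ga_l/2, l1 = (ga_l+gp_l)/2
                l0 = ga_l * 0.5
                l1 = (ga_l + gp_l) * 0.5
                a00 -= -l0 * pc00 - l0 * pc10
                a01 -= -l0 * pc01 - l0 * pc11
                a10 -= l0 * pc00 + l1 * pc10
                a11 -= l0 * pc01 + l1 * pc11
                r0 -= -l0 * pd0 - l0 * pd1
                r1 -= l0 * pd0 + l1 * pd1
            invdet = 1.0 / (a00 * a11 - a01 * a10)
            i00 = a11 * invdet
            i01 = -a01 * invdet
            i10 = -a10 * invdet
            i11 = a00 * invdet
            pd0 = i00 * r0 + i01 * r1
            pd1 = i10 * r0 + i11 * r1
            dp[j, 0] = pd0
            dp[j, 1] = pd1
            if j < n - 1:
                # Up = [[-u0, -u0], [u0, u1]] with u0 = ga_r/2, u1 = (ga_r+gp_r)/2
                u0 = ga_r * 0.5
                u1 = (ga_r + gp_r) * 0.5
                pc00 = -i00 * u0 + i01 * u0
                pc01 = -i00 * u0 + i01 * u1
                pc10 = -i10 * u0 + i11 * u0
                pc11 = -i10 * u0 + i11 * u1
                cp[j, 0, 0] = pc00
                cp[j, 0, 1] = pc01
                cp[j, 1, 0] = pc10
                cp[j, 1, 1] = pc11

        # back substitution
        v[n - 1] = dp[n - 1, 0]
        u[n - 1] = dp[n - 1, 1]
        for j in range(n - 2, -1, -1):
            v[j] = dp[j, 0] - (cp[j, 0, 0] * v[j + 1] + cp[j, 0, 1] * u[j + 1])
            u[j] = dp[j, 1] - (cp[j, 1, 0] * v[j + 1] + cp[j, 1, 1] * u[j + 1])

        vr = v[record_node]
        v_rec[it] = vr
        # large |v| during/just after a strong pulse is a legitimate forced
        # response; flag divergence only for NaN or sustained blow-up with
        # the stimulus off for ≥0.5 ms
        if drive[it] != 0.0:
            steps_since_drive = 0
        else:
            steps_since_drive += 1
        if np.isnan(vr) or (
            (vr > 200.0 or vr < -200.0) and steps_since_drive * dt >= 0.5
        ):
            diverged = True
            break
        if vr >= spike_thresh and v_prev_rec < spike_thresh and (t - last_spike) >= lockout_ms:
            if n_spikes < spike_times.shape[0]:
                spike_times[n_spikes] = t
                n_spikes += 1
            last_spike = t
        v_prev_rec = vr

    v_rec[0] = v_rest
    return spike_times[:n_spikes].copy(), v_rec, diverged
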