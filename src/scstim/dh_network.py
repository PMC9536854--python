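"""Three-node center/surround dorsal-horn network model.

Each node (zone) contains one inhibitory interneuron (IN), one excitatory
interneuron (EX) and one wide-dynamic-range projection neuron (WDR), each
with four compartments (dendrite, soma, axon hillock, axon), plus 15 Aβ,
15 Aδ and 3 C afferent input slots.  Zone 1 is the "center"; zones 2 and 3
are the near and far surround.  Within a node, Aβ input excites IN and WDR
directly, C input drives EX (AMPA/NMDA/NK1), IN inhibits EX and WDR
(GABA_A, glycine) and EX excites WDR; between nodes, the interneurons of
one node project to the WDR (and EX) of the others, the circuit motif that
produces surround inhibition.  Synaptic conductances, time constants and
reversal potentials follow the connection tables below; dorsal-column
axon responses enter through the Aβ slots.

Pain states scale GABA_A conductance (disinhibition), depolarize the
inhibitory reversal potential, add active nociceptors in surround nodes
and weaken Aβ drive onto IN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NEURON_GEOMETRY",
    "SYNAPSE_TABLE",
    "RECEPTOR_KINETICS",
    "NeuronSpec",
    "SynapseSpec",
    "PainState",
    "NetworkModel",
    "build_network",
    "synaptic_conductance",
    "simulate",
    "wdr_change",
    "peripheral_recruitment_experiment",
]

DT_MS = 0.0125
N_ABETA, N_ADELTA, N_C = 15, 15, 3
NEURON_CLASSES = ("EX", "IN", "WDR")
SOMA_SPIKE_THRESHOLD_MV = -20.0
SOMA_SPIKE_LOCKOUT_MS = 2.0
SYNAPTIC_DELAY_MS = 1.0

# --- Geometry: compartment dimensions (µm) per neuron class -----------------
# dendrite cylinder [diameter, length]; soma sphere [diameter];
# hillock cone [initial diameter, final diameter, length]; axon cylinder
# [diameter, length].
NEURON_GEOMETRY = {
    "EX": {"dendrite": (3.0, 300.0), "soma": 25.0, "hillock": (2.0, 1.0, 9.0), "axon": (1.0, 1000.0)},
    "IN": {"dendrite": (3.0, 400.0), "soma": 10.0, "hillock": (1.0, 0.5, 30.0), "axon": (1.0, 1000.0)},
    "WDR": {"dendrite": (2.5, 350.0), "soma": 20.0, "hillock": (2.0, 1.0, 9.0), "axon": (1.0, 1000.0)},
}

# --- Synaptic connections and maximum conductances (nS) ---------------------
# (source, target, receptor, g_max, inter_node)
SYNAPSE_TABLE = [
    ("Abeta", "IN", "AMPA", 14.6, False),
    ("Abeta", "WDR", "AMPA", 24.0, False),
    ("Abeta", "WDR", "NMDA", 0.1, False),
    ("Adelta", "WDR", "AMPA", 24.0, False),
    ("Adelta", "WDR", "NMDA", 0.1, False),
    ("C", "EX", "AMPA", 8.0, False),
    ("C", "EX", "NMDA", 4.0, False),
    ("C", "EX", "NK1", 0.02, False),
    ("C", "WDR", "NK1", 0.014, False),
    ("IN", "EX", "GABA_A", 5.3, False),
    ("IN", "EX", "GABA_A", 3.66, True),
    ("IN", "WDR", "GABA_A", 5.3, False),
    ("IN", "WDR", "Glycine", 5.3, False),
    ("IN", "WDR", "GABA_A", 4.5, True),
    ("IN", "WDR", "Glycine", 4.5, True),
    ("EX", "WDR", "NMDA", 0.21, False),
    ("EX", "WDR", "AMPA", 0.29, False),
    ("EX", "WDR", "NMDA", 0.014, True),
    ("EX", "WDR", "AMPA", 0.14, True),
]

# --- Receptor time constants (ms) and reversal potentials (mV) --------------
RECEPTOR_KINETICS = {
    "AMPA": {"tau1": 0.1, "tau2": 5.0, "e_syn": 0.0},
    "NMDA": {"tau1": 20.0, "tau2": 100.0, "e_syn": 0.0},
    "NK1": {"tau1": 100.0, "tau2": 3000.0, "e_syn": 0.0},
    "GABA_A": {"tau1": 0.1, "tau2": 20.0, "e_syn": -70.0},
    "Glycine": {"tau1": 0.1, "tau2": 10.0, "e_syn": -70.0},
}

# NMDA Mg2+ block: sigmoidal voltage dependence
NMDA_HALF_BLOCK_MV = -20.0
NMDA_SLOPE_MV = 8.0

# --- Channel densities (S/cm²), config-exposed ------------------------------
# Hodgkin–Huxley-type Na / delayed-rectifier K / leak on soma, hillock and
# axon of every neuron; A-type K on the IN soma (transient firing); slow
# Ca + Ca-activated nonspecific cation current on the WDR soma (wind-up).
DEFAULT_CHANNELS = {
    "EX": {"g_na": 0.10, "g_kdr": 0.08, "g_a": 0.0, "g_ca": 0.0, "g_can": 0.0},
    "IN": {"g_na": 0.10, "g_kdr": 0.08, "g_a": 0.04, "g_ca": 0.0, "g_can": 0.0},
    "WDR": {"g_na": 0.10, "g_kdr": 0.08, "g_a": 0.002, "g_ca": 0.002, "g_can": 0.0003},
}
G_LEAK = 1.0e-4  # S/cm²
E_LEAK = -67.0  # mV
CM = 1.0  # µF/cm²
# Effective axial resistivity of the lumped dendrite-to-soma path, per
# neuron class.  The four-compartment reduction collapses an extended
# dendritic tree into one cylinder; the elevated effective resistivity
# restores the cable attenuation of fast synaptic transients that the
# reduction removes, so single Aβ EPSPs sum at the soma instead of each
# forcing a spike.  The projection neuron's tree is the most extensive,
# hence the strongest filtering.
RHO_AXIAL = {"EX": 6.0e6, "IN": 6.0e6, "WDR": 1.2e7}  # Ω·µm
E_NA = 50.0
E_K = -100.0
E_CA = 80.0
E_CAN = -20.0

# compartment order within a neuron
DENDRITE, SOMA, HILLOCK, AXON = 0, 1, 2, 3
# synapse placement: all synapses on the dendrite (as in single-site prior
# circuit models); perisomatic inhibition would give the interneurons an
# absolute veto that masks direct Aβ excitation of the WDR neuron
_TARGET_COMP = {
    "AMPA": DENDRITE,
    "NMDA": DENDRITE,
    "NK1": DENDRITE,
    "GABA_A": DENDRITE,
    "Glycine": DENDRITE,
}


@dataclass(frozen=True)
class NeuronSpec:
    cls: str
    geometry: dict
    channels: dict


@dataclass(frozen=True)
class SynapseSpec:
    source: str
    target: str
    receptor: str
    g_max_nS: float
    tau1_ms: float
    tau2_ms: float
    e_syn_mV: float
    inter_node: bool
    source_node: int
    target_node: int

    def __post_init__(self):
        if not (self.tau2_ms > self.tau1_ms > 0):
            raise ValueError("require tau2 > tau1 > 0")
        if self.g_max_nS < 0:
            raise ValueError("g_max must be nonnegative")


@dataclass
class PainState:
    """Disinhibition axes of a neuropathic pain state.

    Values may be scalars (applied to every node) or length-3 per-node
    arrays.  ``extra_nociceptor_fraction`` only affects surround nodes.
    """

    gaba_scale: float | np.ndarray = 1.0
    e_inh_shift: float | np.ndarray = 0.0
    extra_nociceptor_fraction: float | np.ndarray = 0.0
    abeta_to_in_scale: float | np.ndarray = 1.0

    def per_node(self, name: str) -> np.ndarray:
        v = np.asarray(getattr(self, name), dtype=float)
        return np.broadcast_to(v, (3,)).copy()

    def validate(self) -> None:
        g = self.per_node("gaba_scale")
        if np.any(g < 0.5 - 1e-9) or np.any(g > 1.0 + 1e-9):
            raise ValueError("gaba_scale must lie in [0.5, 1]")
        e = self.per_node("e_inh_shift")
        if np.any(e < -1e-9) or np.any(e > 16.0 + 1e-9) or np.any(np.abs(np.mod(e, 4.0)) > 1e-9):
            raise ValueError("e_inh_shift must be a multiple of 4 in [0, 16] mV")
        f = self.per_node("extra_nociceptor_fraction")
        if np.any(f < -1e-9) or np.any(f > 0.5 + 1e-9):
            raise ValueError("extra_nociceptor_fraction must lie in [0, 0.5]")
        a = self.per_node("abeta_to_in_scale")
        if np.any(a < 0.5 - 1e-9) or np.any(a > 1.0 + 1e-9):
            raise ValueError("abeta_to_in_scale must lie in [0.5, 1]")


def _compartment_areas_um2(geom: dict) -> np.ndarray:
    dd, dl = geom["dendrite"]
    ds = geom["soma"]
    h0, h1, hl = geom["hillock"]
    ad, al = geom["axon"]
    area_dend = np.pi * dd * dl
    area_soma = np.pi * ds**2
    slant = np.hypot(hl, (h0 - h1) / 2.0)
    area_hill = np.pi * (h0 + h1) / 2.0 * slant
    area_axon = np.pi * ad * al
    return np.array([area_dend, area_soma, area_hill, area_axon])


def _axial_g_uS(geom: dict, rho: float) -> np.ndarray:
    """Coupling conductances dendrite–soma, soma–hillock, hillock–axon."""
    dd, dl = geom["dendrite"]
    ds = geom["soma"]
    h0, h1, hl = geom["hillock"]
    ad, al = geom["axon"]

    def half_r(diam, length):
        return rho * (length / 2.0) / (np.pi * diam**2 / 4.0)

    r_dend = half_r(dd, dl)
    r_soma = half_r(ds, ds)  # sphere: use its diameter as path length
    r_hill = half_r((h0 + h1) / 2.0, hl)
    r_axon = half_r(ad, al)
    return 1e6 / np.array([r_dend + r_soma, r_soma + r_hill, r_hill + r_axon])


@dataclass
class NetworkModel:
    """The wired three-node circuit plus its pain state."""

    neurons: list  # 9 NeuronSpec in (node, class) order
    synapses: list  # SynapseSpec instances (internal, between neurons)
    afferent_synapses: list  # SynapseSpec instances fed by afferent slots
    pain_state: PainState
    dt_ms: float = DT_MS

    @property
    def n_nodes(self) -> int:
        return 3

    def neuron_index(self, node: int, cls: str) -> int:
        return node * 3 + NEURON_CLASSES.index(cls)

    def afferent_slot_counts(self) -> dict:
        return {"abeta": N_ABETA, "adelta": N_ADELTA, "c": N_C}


def _double_exp_norm(tau1: float, tau2: float) -> float:
    tp = tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)
    return 1.0 / (np.exp(-tp / tau2) - np.exp(-tp / tau1))


def synaptic_conductance(
    t_ms: np.ndarray, spike_times_ms: np.ndarray, tau1: float, tau2: float, g_max: float
) -> np.ndarray:
    """Normalized double-exponential conductance summed over spikes (nS).

    g(t) = g_max · N · (e^{−(t−t_s)/τ₂} − e^{−(t−t_s)/τ₁}) for t > t_s,
    with N chosen so a single event peaks exactly at g_max.
    """
    if not tau2 > tau1 > 0:
        raise ValueError("require tau2 > tau1 > 0")
    t = np.asarray(t_ms, dtype=float)
    g = np.zeros_like(t)
    norm = _double_exp_norm(tau1, tau2)
    for ts in np.asarray(spike_times_ms, dtype=float):
        dtv = t - ts
        mask = dtv > 0
        g[mask] += g_max * norm * (np.exp(-dtv[mask] / tau2) - np.exp(-dtv[mask] / tau1))
    return g


def build_network(pain_state: PainState | None = None, channels: dict | None = None) -> NetworkModel:
    """Wire the three-node circuit with every synapse-table row.

    The pain state is applied at build time: GABA_A conductances scaled,
    inhibitory reversals shifted, Aβ→IN conductance scaled (all per target
    node); the extra-nociceptor axis is applied when afferent inputs are
    attached (it adds active fibers, not synapses).
    """
    ps = pain_state if pain_state is not None else PainState()
    ps.validate()
    if channels is None:
        channels = DEFAULT_CHANNELS
    gaba = ps.per_node("gaba_scale")
    shift = ps.per_node("e_inh_shift")
    ab_in = ps.per_node("abeta_to_in_scale")

    neurons = [
        NeuronSpec(cls=c, geometry=NEURON_GEOMETRY[c], channels=channels[c])
        for _ in range(3)
        for c in NEURON_CLASSES
    ]

    def kin(receptor: str, target_node: int) -> tuple[float, float, float]:
        k = RECEPTOR_KINETICS[receptor]
        e = k["e_syn"]
        if receptor in ("GABA_A", "Glycine"):
            e = e + shift[target_node]
        return k["tau1"], k["tau2"], e

    synapses: list[SynapseSpec] = []
    afferent: list[SynapseSpec] = []
    for src, tgt, rec, gmax, inter in SYNAPSE_TABLE:
        is_afferent = src in ("Abeta", "Adelta", "C")
        if is_afferent:
            n_slots = {"Abeta": N_ABETA, "Adelta": N_ADELTA, "C": N_C}[src]
            for node in range(3):
                g = gmax
                if src == "Abeta" and tgt == "IN":
                    g = gmax * ab_in[node]
                if rec == "GABA_A":
                    g = g * gaba[node]
                t1, t2, e = kin(rec, node)
                for _slot in range(n_slots):
                    afferent.append(
                        SynapseSpec(src, tgt, rec, g, t1, t2, e, False, node, node)
                    )
        elif not inter:
            for node in range(3):
                g = gmax * gaba[node] if rec == "GABA_A" else gmax
                t1, t2, e = kin(rec, node)
                synapses.append(SynapseSpec(src, tgt, rec, g, t1, t2, e, False, node, node))
        else:
            for src_node in range(3):
                for tgt_node in range(3):
                    if src_node == tgt_node:
                        continue
                    g = gmax * gaba[tgt_node] if rec == "GABA_A" else gmax
                    t1, t2, e = kin(rec, tgt_node)
                    synapses.append(
                        SynapseSpec(src, tgt, rec, g, t1, t2, e, True, src_node, tgt_node)
                    )
    return NetworkModel(neurons=neurons, synapses=synapses, afferent_synapses=afferent, pain_state=ps)


def _merge_trains(a_ms: np.ndarray, b_ms: np.ndarray) -> np.ndarray:
    return np.sort(np.concatenate([np.asarray(a_ms, float), np.asarray(b_ms, float)]))


def simulate(
    network: NetworkModel,
    afferents,
    dc_inputs: dict | None = None,
    duration_s: float = 18.0,
    stim_on_s: float = 10.0,
    record_v: bool = False,
):
    """Integrate the network and return spike trains for all nine neurons.

    Parameters
    ----------
    afferents : AfferentBundle
        Pain-input spike trains (seconds) for every slot of every node.
    dc_inputs : dict, optional
        ``{zone: [spike_times_ms, ...]}`` dorsal-column responses on the
        stimulus clock; they are shifted to stimulation onset
        (``duration_s - stim_on_s``) and merged into the zone's Aβ slots.
    duration_s, stim_on_s : float
        Total simulated time and the stimulation-on period at the end.

    Returns
    -------
    dict with ``spikes`` mapping (node, class) -> spike times (ms),
    ``stim_onset_ms``, and optionally soma voltage traces.
    """
    from scstim._network_engine import run_network, build_engine_arrays

    onset_ms = (duration_s - stim_on_s) * 1e3
    slot_trains = {"Abeta": [], "Adelta": [], "C": []}  # [node][slot] -> ms times
    for node in range(3):
        ab = [np.asarray(t) * 1e3 for t in afferents.abeta[node]]
        if dc_inputs is not None:
            zone = node + 1
            for k, dc in enumerate(dc_inputs.get(zone, [])):
                slot = k % N_ABETA
                ab[slot] = _merge_trains(ab[slot], np.asarray(dc) + onset_ms)
        slot_trains["Abeta"].append(ab)
        slot_trains["Adelta"].append([np.asarray(t) * 1e3 for t in afferents.adelta[node]])
        slot_trains["C"].append([np.asarray(t) * 1e3 for t in afferents.c[node]])

    arrays = build_engine_arrays(network, slot_trains, duration_s * 1e3, baseline_ms=onset_ms)
    spikes_list, v_somas, diverged = run_network(*arrays["args"], record_v)
    spikes = {}
    for idx, (node, cls) in enumerate(arrays["neuron_keys"]):
        spikes[(node + 1, cls)] = spikes_list[idx]
    out = {
        "spikes": spikes,
        "stim_onset_ms": onset_ms,
        "duration_ms": duration_s * 1e3,
        "diverged": [arrays["neuron_keys"][i] for i in np.flatnonzero(diverged)],
    }
    if record_v:
        out["v_soma"] = {
            (node + 1, cls): v_somas[i] for i, (node, cls) in enumerate(arrays["neuron_keys"])
        }
    return out


def save_run(out_dir, result: dict, manifest: dict | None = None) -> None:
    """Write a simulation result as spike-time CSV plus a JSON manifest.

    The CSV has columns ``neuron_id,node,class,t_ms``; the manifest holds
    whatever provenance the caller passes (seeds, pain state, stim spec).
    """
    import csv
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "spikes.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["neuron_id", "node", "class", "t_ms"])
        for (node, cls), times in sorted(result["spikes"].items()):
            nid = f"n{node}_{cls}"
            for t in np.asarray(times):
                w.writerow([nid, node, cls, f"{t:.4f}"])
    meta = {"stim_onset_ms": result.get("stim_onset_ms"), "duration_ms": result.get("duration_ms")}
    if manifest:
        meta.update(manifest)
    (out / "manifest.json").write_text(json.dumps(meta, indent=1, default=str))


def wdr_change(
    baseline_window_ms: tuple[float, float],
    stim_window_ms: tuple[float, float],
    spikes_ms: np.ndarray,
) -> dict:
    """Raw and baseline-normalized change in firing rate.

    raw = rate(stim) − rate(baseline) in Hz; normalized = raw / baseline
    rate (reported as ``nan`` when the baseline is silent).
    """
    b0, b1 = baseline_window_ms
    s0, s1 = stim_window_ms
    if not b1 <= s0:
        raise ValueError("baseline window must precede the stimulation window")
    sp = np.asarray(spikes_ms, dtype=float)
    rate_b = np.sum((sp >= b0) & (sp < b1)) / ((b1 - b0) / 1e3)
    rate_s = np.sum((sp >= s0) & (sp < s1)) / ((s1 - s0) / 1e3)
    raw = rate_s - rate_b
    norm = raw / rate_b if rate_b > 0 else float("nan")
    return {"baseline_hz": rate_b, "stim_hz": rate_s, "raw_delta_hz": raw, "normalized_delta": norm}


def peripheral_recruitment_experiment(
    zone_recruitment_curves: dict,
    amplitudes,
    stim_rate_hz: float = 50.0,
    duration_s: float = 6.0,
    stim_on_s: float = 3.0,
    seed: int = 0,
    pain_state: PainState | None = None,
) -> dict:
    """Zone-1 WDR response to graded peripheral stimulation of each zone.

    ``zone_recruitment_curves`` maps zone -> callable(amplitude) giving the
    fraction of that zone's Aβ/Aδ afferents recruited (monotone, in
    [0, 1]).  Recruited afferents fire phase-locked to the peripheral
    stimulus during the stimulation window.  Returns, per stimulated zone,
    the WDR-1 rate change at each amplitude.
    """
    from scstim.synthetic_data import gen_pain_afferents

    amplitudes = list(amplitudes)
    for zone, curve in zone_recruitment_curves.items():
        fr = [curve(a) for a in amplitudes]
        if np.any(np.diff(fr) < -1e-9) or min(fr) < 0 or max(fr) > 1:
            raise ValueError(f"recruitment curve for zone {zone} must be monotone within [0, 1]")
    onset_ms = (duration_s - stim_on_s) * 1e3
    locked = np.arange(0.0, stim_on_s * 1e3, 1e3 / stim_rate_hz)
    results: dict = {}
    for zone, curve in zone_recruitment_curves.items():
        per_amp = []
        for amp in amplitudes:
            frac = float(curve(amp))
            n_rec = int(round(frac * N_ABETA))
            afferents = gen_pain_afferents(duration_s=duration_s, seed=seed)
            network = build_network(pain_state)
            dc = {zone: [locked.copy() for _ in range(n_rec)]}
            # recruit Aδ alongside Aβ by merging locked spikes into Aδ slots
            for k in range(int(round(frac * N_ADELTA))):
                afferents.adelta[zone - 1][k] = np.sort(
                    np.concatenate([afferents.adelta[zone - 1][k], (locked + onset_ms) / 1e3])
                )
            res = simulate(network, afferents, dc_inputs=dc, duration_s=duration_s, stim_on_s=stim_on_s)
            sp = res["spikes"][(1, "WDR")]
            per_amp.append(
                wdr_change((1e3, onset_ms), (onset_ms, duration_s * 1e3), sp)
            )
        results[zone] = {"amplitudes": amplitudes, "responses": per_amp}
    return results
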