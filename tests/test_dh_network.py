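"""Dorsal-horn network: wiring fidelity, synapse kinetics, simulation contracts."""

import numpy as np
import pytest

from scstim.dh_network import (
    NEURON_GEOMETRY,
    RECEPTOR_KINETICS,
    SYNAPSE_TABLE,
    PainState,
    build_network,
    peripheral_recruitment_experiment,
    simulate,
    synaptic_conductance,
    wdr_change,
)
from scstim.synthetic_data import gen_pain_afferents


class TestWiring:
    def test_afferent_slot_counts(self):
        net = build_network()
        counts = net.afferent_slot_counts()
        assert counts == {"abeta": 15, "adelta": 15, "c": 3}
        # Aβ→IN AMPA: 15 slots per node × 3 nodes
        ab_in = [s for s in net.afferent_synapses if s.source == "Abeta" and s.target == "IN"]
        assert len(ab_in) == 45

    def test_every_table_row_instantiated_with_exact_conductance(self):
        net = build_network()
        pool = net.synapses + net.afferent_synapses
        for src, tgt, rec, gmax, inter in SYNAPSE_TABLE:
            matches = [
                s
                for s in pool
                if s.source == src and s.target == tgt and s.receptor == rec
                and s.inter_node == inter and s.g_max_nS == gmax
            ]
            assert matches, f"{src}->{tgt} {rec} {gmax} missing"
            k = RECEPTOR_KINETICS[rec]
            for s in matches:
                assert s.tau1_ms == k["tau1"]
                assert s.tau2_ms == k["tau2"]
                assert s.e_syn_mV == k["e_syn"]

    def test_internode_synapses_reciprocal(self):
        net = build_network()
        cross = [s for s in net.synapses if s.inter_node]
        # 5 starred (source-class, target-class, receptor) conductances per
        # ordered node pair, 6 ordered pairs
        assert len(cross) == 30
        pairs = {(s.source_node, s.target_node) for s in cross}
        assert pairs == {(i, j) for i in range(3) for j in range(3) if i != j}
        for s in cross:
            mirror = [
                m for m in cross
                if m.source == s.source and m.target == s.target and m.receptor == s.receptor
                and m.source_node == s.target_node and m.target_node == s.source_node
            ]
            assert len(mirror) == 1 and mirror[0].g_max_nS == s.g_max_nS

    def test_geometry_table_dimensions(self):
        assert NEURON_GEOMETRY["EX"]["soma"] == 25.0
        assert NEURON_GEOMETRY["IN"]["soma"] == 10.0
        assert NEURON_GEOMETRY["WDR"]["soma"] == 20.0
        assert NEURON_GEOMETRY["IN"]["dendrite"] == (3.0, 400.0)


class TestPainState:
    def test_gaba_scale_halves_every_gaba_conductance(self):
        base = build_network()
        half = build_network(PainState(gaba_scale=0.5))
        for s0, s1 in zip(base.synapses, half.synapses):
            if s0.receptor == "GABA_A":
                assert s1.g_max_nS == 0.5 * s0.g_max_nS
            else:
                assert s1.g_max_nS == s0.g_max_nS

    def test_reversal_shift_applies_to_inhibitory_synapses(self):
        net = build_network(PainState(e_inh_shift=16.0))
        for s in net.synapses + net.afferent_synapses:
            if s.receptor in ("GABA_A", "Glycine"):
                assert s.e_syn_mV == -70.0 + 16.0
            else:
                assert s.e_syn_mV == RECEPTOR_KINETICS[s.receptor]["e_syn"]

    def test_abeta_to_in_scale(self):
        net = build_network(PainState(abeta_to_in_scale=0.5))
        for s in net.afferent_synapses:
            if s.source == "Abeta" and s.target == "IN":
                assert s.g_max_nS == 0.5 * 14.6

    @pytest.mark.parametrize(
        "bad",
        [
            {"gaba_scale": 0.4},
            {"gaba_scale": 1.2},
            {"e_inh_shift": 5.0},
            {"e_inh_shift": 20.0},
            {"extra_nociceptor_fraction": 0.6},
            {"abeta_to_in_scale": 0.3},
        ],
    )
    def test_malformed_pain_state_rejected(self, bad):
        with pytest.raises(ValueError):
            build_network(PainState(**bad))


class TestSynapticConductance:
    def test_current_zero_at_reversal(self):
        # I = g (V − E): trivially zero at V = E; the conductance itself is
        # positive after a spike
        t = np.linspace(0, 50, 500)
        g = synaptic_conductance(t, [5.0], 0.1, 5.0, 24.0)
        assert g.max() > 0

    def test_single_event_peaks_at_gmax_at_closed_form_time(self):
        tau1, tau2, gmax = 0.1, 5.0, 24.0
        t_peak = tau1 * tau2 / (tau2 - tau1) * np.log(tau2 / tau1)
        t = np.linspace(0, 60, 200001)
        g = synaptic_conductance(t, [0.0], tau1, tau2, gmax)
        np.testing.assert_allclose(g.max(), gmax, rtol=1e-5)
        np.testing.assert_allclose(t[np.argmax(g)], t_peak, atol=1e-3)

    def test_distant_spikes_superpose(self):
        tau1, tau2, gmax = 0.1, 5.0, 10.0
        t = np.linspace(0, 300, 300001)
        g = synaptic_conductance(t, [50.0, 200.0], tau1, tau2, gmax)
        peaks = [g[(t > 45) & (t < 70)].max(), g[(t > 195) & (t < 220)].max()]
        np.testing.assert_allclose(peaks, gmax, rtol=1e-4)

    def test_invalid_time_constants_rejected(self):
        with pytest.raises(ValueError):
            synaptic_conductance(np.array([0.0]), [0.0], 5.0, 5.0, 1.0)


class TestWdrChange:
    def test_drop_from_10_to_5_hz(self):
        spikes = np.concatenate([np.arange(0, 1000, 100), np.arange(1000, 2000, 200)])
        out = wdr_change((0, 1000), (1000, 2000), spikes)
        assert out["raw_delta_hz"] == -5.0
        assert out["normalized_delta"] == -0.5

    def test_unchanged_rate_gives_zero(self):
        spikes = np.arange(0, 2000, 100.0)
        out = wdr_change((0, 1000), (1000, 2000), spikes)
        assert out["raw_delta_hz"] == 0.0 and out["normalized_delta"] == 0.0

    def test_empty_stim_window(self):
        spikes = np.arange(0, 1000, 100.0)
        out = wdr_change((0, 1000), (1000, 2000), spikes)
        assert out["raw_delta_hz"] == -10.0
        assert out["normalized_delta"] == -1.0

    def test_zero_baseline_reported_missing(self):
        out = wdr_change((0, 1000), (1000, 2000), np.array([1500.0]))
        assert np.isnan(out["normalized_delta"])

    def test_windows_must_be_ordered(self):
        with pytest.raises(ValueError):
            wdr_change((1000, 2000), (0, 1000), np.array([]))


class _SilentAfferents:
    abeta = [[np.empty(0)] * 15 for _ in range(3)]
    adelta = [[np.empty(0)] * 15 for _ in range(3)]
    c = [[np.empty(0)] * 3 for _ in range(3)]


class TestSimulation:
    def test_quiescent_without_afferent_drive(self):
        net = build_network()
        res = simulate(net, _SilentAfferents(), duration_s=3.0, stim_on_s=1.0)
        rate = len(res["spikes"][(1, "WDR")]) / 3.0
        assert rate < 1.0

    def test_pain_input_drives_sustained_wdr_firing(self):
        aff = gen_pain_afferents(duration_s=5.0, seed=3)
        net = build_network()
        res = simulate(net, aff, duration_s=5.0, stim_on_s=2.0)
        spikes = res["spikes"][(1, "WDR")]
        assert len(spikes) / 5.0 > 5.0
        # firing persists through the whole window, not a transient
        assert np.sum(spikes > 2500) > 5

    def test_inhibition_knockout_raises_wdr_rate(self):
        # bicuculline analog: with surround drive engaging the interneurons,
        # removing GABA_A + glycine conductances releases the WDR neuron
        from dataclasses import replace

        aff = gen_pain_afferents(duration_s=4.0, seed=5)
        dc = {2: [np.arange(0.0, 2000.0, 1000.0 / 90.0)] * 5}
        r1 = simulate(build_network(), aff, dc_inputs=dc, duration_s=4.0, stim_on_s=2.0)
        net2 = build_network()
        net2.synapses = [
            replace(s, g_max_nS=0.0) if s.receptor in ("GABA_A", "Glycine") else s
            for s in net2.synapses
        ]
        r2 = simulate(net2, aff, dc_inputs=dc, duration_s=4.0, stim_on_s=2.0)
        w1 = np.asarray(r1["spikes"][(1, "WDR")])
        w2 = np.asarray(r2["spikes"][(1, "WDR")])
        assert np.sum(w2 >= 2000) > np.sum(w1 >= 2000)

    def test_seed_determinism(self):
        aff = gen_pain_afferents(duration_s=3.0, seed=7)
        r1 = simulate(build_network(), aff, duration_s=3.0, stim_on_s=1.0)
        r2 = simulate(build_network(), aff, duration_s=3.0, stim_on_s=1.0)
        for key in r1["spikes"]:
            np.testing.assert_array_equal(r1["spikes"][key], r2["spikes"][key])


class TestRunOutput:
    def test_spike_csv_and_manifest_roundtrip(self, tmp_path):
        import json
        import pandas as pd
        from scstim.dh_network import save_run

        result = {
            "spikes": {(1, "WDR"): np.array([10.0, 20.5]), (2, "IN"): np.array([5.25])},
            "stim_onset_ms": 3000.0,
            "duration_ms": 6000.0,
        }
        save_run(tmp_path, result, manifest={"seed": 7})
        df = pd.read_csv(tmp_path / "spikes.csv")
        assert list(df.columns) == ["neuron_id", "node", "class", "t_ms"]
        assert len(df) == 3
        assert set(df["class"]) == {"WDR", "IN"}
        meta = json.loads((tmp_path / "manifest.json").read_text())
        assert meta["seed"] == 7 and meta["stim_onset_ms"] == 3000.0


class TestPeripheralRecruitment:
    def test_non_monotone_curve_rejected(self):
        with pytest.raises(ValueError):
            peripheral_recruitment_experiment(
                {1: lambda a: 1.0 - a}, [0.0, 0.5, 1.0], duration_s=1.0
            )

    def test_center_excites_surround_inhibits(self):
        curves = {1: lambda a: a, 3: lambda a: a}
        res = peripheral_recruitment_experiment(
            curves, [0.0, 1.0], duration_s=5.0, stim_on_s=2.0, seed=2
        )
        z1 = res[1]["responses"]
        z3 = res[3]["responses"]
        # relative to the zero-recruitment control (which carries the slow
        # burst-episode fluctuations of the pain input), center stimulation
        # excites WDR-1 while far-surround stimulation inhibits it
        assert z1[1]["raw_delta_hz"] > z1[0]["raw_delta_hz"]
        assert z3[1]["raw_delta_hz"] < z3[0]["raw_delta_hz"] - 5.0
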