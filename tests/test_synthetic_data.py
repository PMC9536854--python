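"""Generator statistics and determinism."""

import numpy as np
import pytest
from scipy import stats

from scstim.dh_network import PainState
from scstim.synthetic_data import (
    SyntheticUnit,
    bursting_sustained_rate_hz,
    gen_pain_afferents,
    gen_recorded_session,
    gen_unit_waveform,
    random_unit_params,
    sample_pain_states,
    _two_gaussian,
)


class TestPainAfferents:
    def test_pooled_a_fiber_rate(self):
        # ≥200 A-fiber trains of 100 s
        n_spikes = 0
        n_trains = 0
        for seed in range(7):
            b = gen_pain_afferents(node_count=3, duration_s=100.0, seed=seed)
            for node in range(3):
                for tr in b.abeta[node] + b.adelta[node]:
                    n_spikes += len(tr)
                    n_trains += 1
        assert n_trains >= 200
        rate = n_spikes / (n_trains * 100.0)
        assert abs(rate - 2.2) < 0.1

    def test_pooled_c_fiber_rate(self):
        # the per-train gamma rate heterogeneity (SD ≈ 1.06 Hz) dominates
        # the pooled-rate error, so precision comes from the train count
        n_spikes = 0
        n_trains = 0
        for seed in range(60):
            b = gen_pain_afferents(node_count=3, duration_s=100.0, seed=seed)
            for node in range(3):
                for tr in b.c[node]:
                    n_spikes += len(tr)
                    n_trains += 1
        assert n_trains >= 200
        assert abs(n_spikes / (n_trains * 100.0) - 1.5) < 0.1

    def test_burst_statistics(self):
        # ≥10³ bursts required; collect ~5× that so the Monte-Carlo SE of
        # the inter-burst mean (≈551/√n ms) is well inside the ±20 ms band
        sizes = []
        gaps = []
        seed = 0
        while len(gaps) < 5000:
            b = gen_pain_afferents(node_count=3, duration_s=200.0, seed=seed)
            for info in b.burst_info:
                sizes.extend(info.n_spikes)
                gaps.extend(info.inter_burst_gaps_s)
            seed += 1
        assert len(sizes) >= 1000
        assert abs(np.mean(sizes) - 6.0) < 0.2
        assert abs(np.mean(gaps) * 1e3 - 551.0) < 20.0

    def test_one_third_of_a_fibers_burst(self):
        b = gen_pain_afferents(duration_s=10.0, seed=4)
        for node in range(3):
            n_burst = len(b.bursting_abeta[node]) + len(b.bursting_adelta[node])
            assert n_burst == 30 // 3

    def test_bimodal_isi_separation(self):
        # intra-burst (30 ms) and inter-burst (551 ms) regimes differ by >5×
        assert 551.0 / 30.0 > 5.0
        b = gen_pain_afferents(duration_s=200.0, seed=9)
        isis = []
        for node in range(3):
            for i in b.bursting_abeta[node]:
                isis.extend(np.diff(b.abeta[node][i]))
        isis = np.asarray(isis)
        short = isis[isis < 0.1]
        lng = isis[isis > 0.2]
        assert len(short) > 10 and len(lng) > 10
        assert np.mean(lng) / np.mean(short) > 5.0

    def test_zero_duration_gives_empty_trains(self):
        b = gen_pain_afferents(duration_s=0.0, seed=1)
        assert all(len(tr) == 0 for node in range(3) for tr in b.abeta[node])

    def test_seed_determinism(self):
        b1 = gen_pain_afferents(duration_s=20.0, seed=42)
        b2 = gen_pain_afferents(duration_s=20.0, seed=42)
        for node in range(3):
            for t1, t2 in zip(b1.abeta[node], b2.abeta[node]):
                np.testing.assert_array_equal(t1, t2)

    def test_sustained_burst_rate_exceeds_population_mean(self):
        # the stated burst parameters imply ~8.6 Hz inside episodes
        assert bursting_sustained_rate_hz() > 2.2


class TestPainStates:
    def test_latin_hypercube_stratification(self):
        states = sample_pain_states(30, seed=0)
        assert len(states) == 30
        gaba = np.sort([s.gaba_scale for s in states])
        # exactly one sample per stratum of width 0.5/30
        strata = np.floor((gaba - 0.5) / (0.5 / 30)).astype(int)
        assert sorted(strata.tolist()) == list(range(30))
        noci = np.sort([s.extra_nociceptor_fraction for s in states])
        strata = np.floor(noci / (0.5 / 30)).astype(int)
        assert sorted(strata.tolist()) == list(range(30))

    def test_reversal_shift_quantized(self):
        states = sample_pain_states(30, seed=1)
        assert all(s.e_inh_shift in (0.0, 4.0, 8.0, 12.0, 16.0) for s in states)

    def test_axis_ranges(self):
        states = sample_pain_states(30, seed=2)
        assert all(0.5 <= s.gaba_scale <= 1.0 for s in states)
        assert all(0.5 <= s.abeta_to_in_scale <= 1.0 for s in states)
        assert all(0.0 <= s.extra_nociceptor_fraction <= 0.5 for s in states)
        for s in states:
            s.validate()

    def test_marginal_uniformity_ks(self):
        states = sample_pain_states(30, seed=3)
        for attr, lo, width in (
            ("gaba_scale", 0.5, 0.5),
            ("extra_nociceptor_fraction", 0.0, 0.5),
            ("abeta_to_in_scale", 0.5, 0.5),
        ):
            u = (np.array([getattr(s, attr) for s in states]) - lo) / width
            d = stats.kstest(u, "uniform").statistic
            crit = 1.63 / np.sqrt(30)  # α = 0.01
            assert d < crit


class TestWaveforms:
    def test_noiseless_waveform_matches_model_exactly(self):
        params = random_unit_params("pIN", np.random.default_rng(0))
        t, v = gen_unit_waveform("pIN", params, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(v, _two_gaussian(t, *params), rtol=0, atol=0)

    def test_zero_amplitude_waveform_is_flat(self):
        t, v = gen_unit_waveform("pEX", (0.0, 0.4, 0.1, 0.0, 0.6, 0.1), 0.0, seed=0)
        assert np.all(v == 0)

    def test_sampling_grid(self):
        t, v = gen_unit_waveform("pEX", (-1.0, 0.4, 0.1, -0.05, 0.7, 0.1), 0.0, seed=0)
        assert len(t) == 48  # 1.2 ms at 40 kHz
        np.testing.assert_allclose(np.diff(t), 1 / 40.0)

    def test_class_invariants_enforced(self):
        with pytest.raises(ValueError):
            gen_unit_waveform("pEX", (-1.0, 0.4, 0.1, 0.9, 0.7, 0.1), 0.0, seed=0)
        with pytest.raises(ValueError):
            gen_unit_waveform("pIN", (-1.0, 0.4, 0.1, -0.9, 0.7, 0.1), 0.0, seed=0)


class TestRecordedSession:
    def _unit(self, factor, rate=10.0):
        rng = np.random.default_rng(1)
        return SyntheticUnit(
            unit_id="u0",
            cls="pEX",
            params=random_unit_params("pEX", rng),
            baseline_rate_hz=rate,
            modulation={40.0: factor},
            noise_sd=0.01,
        )

    def test_factor_zero_empties_stim_window(self):
        recs = gen_recorded_session([self._unit(0.0)], [40.0], seed=0)
        assert len(recs[0].stim_spikes_s[40.0]) == 0

    def test_rates_follow_modulation(self):
        recs = gen_recorded_session([self._unit(0.3, rate=20.0)], [40.0], seed=5, stim_s=100.0,
                                    baseline_s=100.0)
        r = recs[0]
        base_rate = len(r.baseline_spikes_s) / 100.0
        stim_rate = len(r.stim_spikes_s[40.0]) / 100.0
        assert abs(base_rate - 20.0) < 2.0
        assert abs(stim_rate - 6.0) < 1.2

    def test_pulse_times_recorded(self):
        recs = gen_recorded_session([self._unit(1.0)], [40.0], seed=0, stim_frequency_hz=90.0)
        pulses = recs[0].pulse_times_s[40.0]
        np.testing.assert_allclose(np.diff(pulses), 1 / 90.0)

    def test_session_serialization_roundtrip(self, tmp_path):
        import json
        import pandas as pd
        from scstim.synthetic_data import save_session

        unit = self._unit(0.5)
        recs = gen_recorded_session([unit], [40.0], seed=3, baseline_s=20.0, stim_s=10.0)
        save_session(recs, [unit], tmp_path)
        spikes = pd.read_csv(tmp_path / "spikes.csv")
        n_expected = len(recs[0].baseline_spikes_s) + len(recs[0].stim_spikes_s[40.0])
        assert len(spikes) == n_expected
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert truth["units"]["u0"]["class"] == "pEX"
        assert truth["units"]["u0"]["modulation"]["40.0"] == 0.5
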