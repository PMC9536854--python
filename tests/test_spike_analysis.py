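"""Analysis pipeline: bin widths, responder statistics, clustering, waveforms."""

import numpy as np
import pytest

from scstim import spike_analysis as sa
from scstim.synthetic_data import SyntheticUnit, UnitRecording, gen_recorded_session, random_unit_params


def _recording(baseline_rate, stim_rate, seed=0, dur=30.0, unit_id="u"):
    rng = np.random.default_rng(seed)
    base = np.sort(rng.uniform(0, dur, rng.poisson(baseline_rate * dur)))
    stim = np.sort(rng.uniform(0, dur, rng.poisson(stim_rate * dur)))
    return UnitRecording(
        unit_id=unit_id,
        waveform_t_ms=np.arange(48) / 40.0,
        waveform=np.zeros(48),
        baseline_spikes_s=base,
        stim_spikes_s={40.0: stim},
        pulse_times_s={40.0: np.empty(0)},
        stim_duration_s=dur,
        baseline_duration_s=dur,
    )


class TestOptimalBinwidth:
    def test_stationary_poisson_prefers_wide_bins(self):
        # for a rate-constant train the cost ~ rate/width: minimized at the
        # widest candidate (no PSTH structure to resolve)
        rng = np.random.default_rng(1)
        widths = [
            sa.optimal_binwidth(np.sort(rng.uniform(0, 60, 1200)))
            for _ in range(5)
        ]
        assert all(w >= 1000.0 for w in widths)
        assert max(widths) / min(widths) <= 2.0

    def test_time_rescaling_scales_optimal_width(self):
        # cost-function property: t -> 2t maps C(w) -> C(2w)/4, preserving
        # the argmin location up to the grid
        rng = np.random.default_rng(2)
        # structured train: 4 Hz bursts of activity
        t = np.sort(np.concatenate([rng.normal(m, 0.02, 30) for m in np.arange(0.5, 60, 2.0)]))
        t = t[(t > 0) & (t < 60)]
        cands = np.array([25.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1600.0])
        w1 = sa.optimal_binwidth(t, candidate_widths_ms=cands)
        w2 = sa.optimal_binwidth(2 * t, candidate_widths_ms=2 * cands)
        assert w2 == 2 * w1

    def test_sparse_train_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            w = sa.optimal_binwidth(np.array([1.0]))
        assert w == 500.0


class TestResponderTest:
    def test_identical_statistics_is_nonresponder(self):
        rng = np.random.default_rng(3)
        spikes = np.sort(rng.uniform(0, 30, 300))
        rec = _recording(10, 10, seed=3)
        rec.baseline_spikes_s = spikes
        rec.stim_spikes_s[40.0] = spikes.copy()
        res = sa.responder_test(rec, 40.0, 500.0)
        assert not res.responder

    def test_threefold_excitation_detected(self):
        # analytic Poisson oracle: with 10->30 Hz and 500 ms bins, each bin's
        # z ≈ (15 − 5)/√5 ≈ 4.5 — far above 1.96, so ≥3 consecutive
        # significant bins are certain in practice
        rec = _recording(10, 30, seed=4)
        res = sa.responder_test(rec, 40.0, 500.0)
        assert res.responder and res.direction == "excited"
        assert res.raw_delta_hz > 10

    def test_strong_inhibition_detected(self):
        rec = _recording(20, 2, seed=5)
        res = sa.responder_test(rec, 40.0, 500.0)
        assert res.responder and res.direction == "inhibited"

    def test_two_consecutive_bins_insufficient(self):
        z = np.array([0.1, 2.5, 2.5, 0.3, 2.5, 0.1, -2.2, -2.5, 0.0])
        assert sa._longest_significant_run(z) == 2
        z3 = np.array([0.1, 2.5, 2.5, 1.97, 0.3])
        assert sa._longest_significant_run(z3) == 3

    def test_artifact_blanking_is_phase_matched(self):
        # spikes landing within the blanking window are dropped from both
        # stimulation and baseline trains
        pulses = np.arange(0.0, 30.0, 1.0 / 90.0)
        rec = _recording(10, 10, seed=6)
        rec.pulse_times_s = {40.0: pulses}
        res_blank = sa.responder_test(rec, 40.0, 500.0, blank_ms=1.0)
        assert not res_blank.responder

    def test_zero_baseline_variance_uses_poisson_fallback(self):
        rec = _recording(0.0, 10, seed=7)
        rec.baseline_spikes_s = np.arange(0.25, 30.0, 0.5)  # one spike per bin exactly
        res = sa.responder_test(rec, 40.0, 500.0)
        assert res.poisson_fallback


class TestNormalization:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([2, -4, 1], [0.5, -1.0, 0.25]),
            ([0, 0], [0.0, 0.0]),
            ([-3], [-1.0]),
            ([5, 5], [1.0, 1.0]),
        ],
    )
    def test_hand_computed_vectors(self, raw, expected):
        np.testing.assert_allclose(sa.normalize_responses(np.array(raw, float)), expected)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sa.normalize_responses(np.array([]))


class _Unit:
    def __init__(self, uid, rate, dur=30.0):
        self.unit_id = uid
        self.baseline_duration_s = dur
        self.baseline_spikes_s = np.arange(0, dur, 1.0 / rate) if rate > 0 else np.empty(0)


class _Res:
    def __init__(self, responder):
        self.responder = responder


class TestInclusionFilter:
    def test_rules(self):
        units = [_Unit("slow_responder", 1.4), _Unit("ok_responder", 5.0), _Unit("ok_silent", 5.0)]
        table = {
            "slow_responder": [_Res(True), _Res(False)],
            "ok_responder": [_Res(False), _Res(True)],
            "ok_silent": [_Res(False), _Res(False)],
        }
        kept = sa.inclusion_filter(units, table)
        assert [u.unit_id for u in kept] == ["ok_responder"]

    def test_boundary_rate_included(self):
        units = [_Unit("edge", 1.5)]
        kept = sa.inclusion_filter(units, {"edge": [_Res(True)]})
        assert len(kept) == 1


def _fcm_oracle(x, k, m=2.0, seed=0, iters=300):
    """Brute-force FCM: plain alternating updates from one random init."""
    rng = np.random.default_rng(seed)
    u = rng.dirichlet(np.ones(k), size=len(x))
    for _ in range(iters):
        um = u**m
        c = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = np.maximum(((x[:, None, :] - c[None]) ** 2).sum(-1), 1e-12)
        u = d2 ** (-1 / (m - 1))
        u /= u.sum(axis=1, keepdims=True)
    return c, u, float((u**m * d2).sum())


class TestFuzzyCMeans:
    def test_membership_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 2))
        _, u, _ = sa.fuzzy_cmeans(x, 3, seed=1)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)

    def test_matches_bruteforce_objective_on_20_points(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(0, 0.5, (10, 2)), rng.normal(5, 0.5, (10, 2))])
        _, _, obj = sa.fuzzy_cmeans(x, 2, seed=0)
        _, _, obj_oracle = _fcm_oracle(x, 2, seed=0)
        np.testing.assert_allclose(obj, obj_oracle, rtol=1e-4)

    def test_duplication_stability(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 0.5, (10, 2)), rng.normal(5, 0.5, (10, 2))])
        _, u1, _ = sa.fuzzy_cmeans(x, 2, seed=0)
        _, u2, _ = sa.fuzzy_cmeans(np.concatenate([x, x]), 2, seed=0)
        l1 = np.argmax(u1, axis=1)
        l2a, l2b = np.argmax(u2[:20], axis=1), np.argmax(u2[20:], axis=1)
        np.testing.assert_array_equal(l2a, l2b)
        # same partition up to label permutation
        agreement = np.mean(l1 == l2a)
        assert agreement in (0.0, 1.0) or agreement > 0.99 or agreement < 0.01


class TestClusterResponses:
    def test_separated_blobs_select_k2_perfectly(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.05, (20, 4)) + np.array([1, 1, -1, -1])
        b = rng.normal(0, 0.05, (20, 4)) + np.array([-1, -1, 1, 1])
        res = sa.cluster_responses(np.vstack([a, b]), seed=0)
        assert res.best_k_silhouette == 2
        labels = res.hard_labels[2]
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_membership_constraint_all_k(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(30, 4))
        res = sa.cluster_responses(x, seed=0)
        for k, u in res.memberships.items():
            np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-9)
            np.testing.assert_array_equal(res.hard_labels[k], np.argmax(u, axis=1))

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            sa.cluster_responses(np.zeros((3, 4)))


class TestWaveformFit:
    def test_noiseless_roundtrip_within_1pct(self):
        rng = np.random.default_rng(9)
        for cls in ("pEX", "pIN"):
            params = random_unit_params(cls, rng)
            t = np.arange(48) / 40.0
            from scstim.synthetic_data import _two_gaussian

            v = _two_gaussian(t, *params)
            fit = sa.fit_waveform(t, v)
            recon = _two_gaussian(t, *fit.params)
            rel = np.linalg.norm(v - recon) / np.linalg.norm(v)
            assert rel < 0.01

    def test_flat_waveform_unclassifiable(self):
        fit = sa.fit_waveform(np.arange(48) / 40.0, np.zeros(48))
        assert not fit.classifiable
        label, conf = sa.classify_unit(fit)
        assert label == "unclassified"

    def test_single_gaussian_gives_one_null_amplitude(self):
        t = np.arange(48) / 40.0
        v = -np.exp(-(((t - 0.5) / 0.1) ** 2))
        fit = sa.fit_waveform(t, v)
        a1, _, _, a2, _, _ = fit.params
        assert min(abs(a1), abs(a2)) < 0.05 * max(abs(a1), abs(a2))

    def test_short_waveform_rejected(self):
        with pytest.raises(ValueError):
            sa.fit_waveform(np.arange(10), np.zeros(10))


@pytest.fixture(scope="session")
def waveform_classifier():
    return sa.train_waveform_classifier(seed=0, n_per_class=150)


class TestClassification:
    def test_strong_monophasic_is_pex_with_high_confidence(self, waveform_classifier):
        t = np.arange(48) / 40.0
        from scstim.synthetic_data import _two_gaussian

        v = _two_gaussian(t, -1.0, 0.35, 0.08, -0.05, 0.7, 0.15)
        fit = sa.fit_waveform(t, v)
        label, conf = sa.classify_unit(fit, classifier=waveform_classifier)
        assert label == "pEX" and conf > 0.9

    def test_balanced_biphasic_is_pin(self, waveform_classifier):
        t = np.arange(48) / 40.0
        from scstim.synthetic_data import _two_gaussian

        v = _two_gaussian(t, -1.0, 0.35, 0.08, 1.0, 0.65, 0.15)
        fit = sa.fit_waveform(t, v)
        label, _ = sa.classify_unit(fit, classifier=waveform_classifier)
        assert label == "pIN"

    def test_low_posterior_is_unclassified(self, waveform_classifier):
        fit = sa.WaveformFit(params=(0,) * 6, residual_norm=0.0, features={}, classifiable=False)
        assert sa.classify_unit(fit, classifier=waveform_classifier)[0] == "unclassified"
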