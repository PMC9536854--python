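"""Generators for every synthetic input the pipeline consumes.

Four families of inputs are produced, all seed-deterministic:

* neuropathic "pain" afferent spike trains (A-fiber population mean
  2.2 Hz, C-fiber 1.5 Hz, episodic bursting in one third of A-fibers);
* Latin-hypercube samples of dorsal-horn pain states;
* extracellular unit waveforms as a sum of two Gaussians (the monophasic /
  biphasic dichotomy behind pEX / pIN classification);
* emulated recording sessions with known stimulation-locked rate
  modulation, for closed-loop validation of the analysis pipeline.

Bursting model.  The stated burst statistics (intra-burst ISI mean 30 ms,
inter-burst interval mean 551 ms, mean 6 spikes per burst) imply ~8.6 Hz
of sustained bursting, far above the 2.2 Hz population mean, so bursting
cannot be continuous.  Bursting fibers here alternate between quiescent
periods and bursting episodes; within an episode bursts recur with
exponential inter-burst gaps (mean 551 ms), intra-burst ISIs are
exponential (mean 30 ms) and burst sizes Poisson (mean 6, minimum 2).
The fraction of time spent bursting is set per fiber so its long-run mean
rate equals its drawn target rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scstim.dh_network import PainState

__all__ = [
    "AfferentBundle",
    "SyntheticUnit",
    "BurstInfo",
    "gen_pain_afferents",
    "sample_pain_states",
    "gen_unit_waveform",
    "gen_recorded_session",
]

A_FIBER_MEAN_HZ = 2.2
C_FIBER_MEAN_HZ = 1.5
RATE_GAMMA_SHAPE = 2.0  # per-fiber rate heterogeneity
BURST_INTRA_ISI_MS = 30.0
BURST_INTER_MS = 551.0
BURST_MEAN_SPIKES = 6.0
BURST_MIN_SPIKES = 2
BURST_EPISODE_MEAN_S = 5.0
N_ABETA, N_ADELTA, N_C = 15, 15, 3

WAVEFORM_FS_HZ = 40_000.0
WAVEFORM_DUR_MS = 1.2


@dataclass
class BurstInfo:
    """Realized burst bookkeeping of one bursting train."""

    start_times_s: np.ndarray
    n_spikes: np.ndarray
    inter_burst_gaps_s: np.ndarray  # gaps between consecutive bursts within an episode


@dataclass
class AfferentBundle:
    """Per-node afferent trains: 15 Aβ + 15 Aδ + 3 C spike-time arrays (s)."""

    abeta: list  # [node][fiber] -> spike times (s)
    adelta: list
    c: list
    bursting_abeta: list  # [node] -> indices of bursting Aβ fibers
    bursting_adelta: list
    burst_info: list  # BurstInfo per bursting train
    seed: int
    duration_s: float

    def node_trains(self, node: int) -> dict[str, list]:
        return {"abeta": self.abeta[node], "adelta": self.adelta[node], "c": self.c[node]}


def _poisson_train(rate_hz: float, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    if rate_hz <= 0 or duration_s <= 0:
        return np.empty(0)
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def _burst_cycle_mean_s() -> float:
    """Expected duration of one burst-plus-gap cycle during an episode."""
    mean_isis = BURST_MEAN_SPIKES - 1.0  # mean number of intra-burst intervals
    return (mean_isis * BURST_INTRA_ISI_MS + BURST_INTER_MS) / 1e3


def bursting_sustained_rate_hz() -> float:
    """Mean rate while a fiber is inside a bursting episode (≈8.6 Hz)."""
    return BURST_MEAN_SPIKES / _burst_cycle_mean_s()


BURSTS_PER_EPISODE_MEAN = 7.0


def _bursting_train(
    target_rate_hz: float, duration_s: float, rng: np.random.Generator
) -> tuple[np.ndarray, BurstInfo]:
    """Episodic burst train with long-run mean rate ``target_rate_hz``.

    Each episode contains a Poisson-distributed number of bursts (mean 7,
    minimum 1) separated by exponential inter-burst gaps (mean 551 ms);
    the quiescent interval after each episode is drawn so the expected
    overall rate equals the target.
    """
    if target_rate_hz <= 0 or duration_s <= 0:
        return np.empty(0), BurstInfo(np.empty(0), np.empty(0, dtype=int), np.empty(0))
    mean_burst_dur = (BURST_MEAN_SPIKES - 1.0) * BURST_INTRA_ISI_MS / 1e3
    spikes: list[float] = []
    b_start: list[float] = []
    b_n: list[int] = []
    b_gaps: list[float] = []
    # burn-in of two episode-plus-quiet cycles plus a random phase before
    # t = 0: starting the window mid-first-cycle would length-bias the
    # sampled cycles (inspection paradox) and inflate the realized rate
    expected_cycle_s = BURSTS_PER_EPISODE_MEAN * BURST_MEAN_SPIKES / target_rate_hz
    t = -(2.0 * expected_cycle_s + rng.uniform(0.0, expected_cycle_s))
    while t < duration_s:
        n_b = max(1, int(rng.poisson(BURSTS_PER_EPISODE_MEAN)))
        episode_t0 = t
        episode_spikes = 0
        prev_recorded = False
        for k in range(n_b):
            n_sp = max(BURST_MIN_SPIKES, int(rng.poisson(BURST_MEAN_SPIKES)))
            isis = rng.exponential(BURST_INTRA_ISI_MS / 1e3, size=n_sp - 1)
            times = t + np.concatenate([[0.0], np.cumsum(isis)])
            kept = times[(times >= 0.0) & (times < duration_s)]
            spikes.extend(kept)
            if 0.0 <= t < duration_s:
                b_start.append(t)
                b_n.append(n_sp)
                if k > 0 and prev_recorded:
                    b_gaps.append(gap)
                prev_recorded = True
            else:
                prev_recorded = False
            episode_spikes += n_sp
            burst_end = t + float(np.sum(isis))
            gap = rng.exponential(BURST_INTER_MS / 1e3)
            t = burst_end + gap
        # quiescent period: expected episode spikes over target rate minus
        # the expected time already spent bursting
        episode_time = t - episode_t0
        quiet_mean = max(episode_spikes / target_rate_hz - episode_time, 0.0)
        t += rng.exponential(quiet_mean) if quiet_mean > 0 else 0.0
    return (
        np.sort(np.asarray(spikes)),
        BurstInfo(np.asarray(b_start), np.asarray(b_n, dtype=int), np.asarray(b_gaps)),
    )


def _draw_rates(n: int, pop_mean: float, rng: np.random.Generator) -> np.ndarray:
    scale = pop_mean / RATE_GAMMA_SHAPE
    return rng.gamma(RATE_GAMMA_SHAPE, scale, size=n)


def gen_pain_afferents(
    node_count: int = 3,
    duration_s: float = 18.0,
    seed: int = 0,
) -> AfferentBundle:
    """Neuropathic pain input trains for every afferent slot of the network.

    Per node: 15 Aβ + 15 Aδ (A-fiber population mean 2.2 Hz) and 3 C
    fibers (population mean 1.5 Hz).  One third of the A-fibers in each
    node carry episodic bursting; their long-run mean rate still follows
    the 2.2 Hz population distribution.
    """
    rng = np.random.default_rng(seed)
    abeta, adelta, c = [], [], []
    bursting_ab, bursting_ad, infos = [], [], []
    for _ in range(node_count):
        n_a = N_ABETA + N_ADELTA
        rates_a = _draw_rates(n_a, A_FIBER_MEAN_HZ, rng)
        n_burst = n_a // 3
        burst_idx = rng.choice(n_a, size=n_burst, replace=False)
        trains_a: list[np.ndarray] = []
        for i in range(n_a):
            if i in burst_idx:
                tr, info = _bursting_train(rates_a[i], duration_s, rng)
                infos.append(info)
            else:
                tr = _poisson_train(rates_a[i], duration_s, rng)
            trains_a.append(tr)
        abeta.append(trains_a[:N_ABETA])
        adelta.append(trains_a[N_ABETA:])
        bursting_ab.append([i for i in burst_idx if i < N_ABETA])
        bursting_ad.append([i - N_ABETA for i in burst_idx if i >= N_ABETA])
        rates_c = _draw_rates(N_C, C_FIBER_MEAN_HZ, rng)
        c.append([_poisson_train(r, duration_s, rng) for r in rates_c])
    return AfferentBundle(
        abeta=abeta,
        adelta=adelta,
        c=c,
        bursting_abeta=bursting_ab,
        bursting_adelta=bursting_ad,
        burst_info=infos,
        seed=seed,
        duration_s=duration_s,
    )


def sample_pain_states(n: int = 30, seed: int = 0) -> list[PainState]:
    """Latin-hypercube sample of pain states.

    Four axes: GABA_A conductance scale [0.5, 1], inhibitory reversal
    shift [0, 16] mV (snapped to multiples of 4), extra active nociceptor
    fraction in surround nodes [0, 0.5], Aβ→IN conductance scale [0.5, 1].
    Each axis is partitioned into ``n`` strata with one sample per stratum.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    rng = np.random.default_rng(seed)
    # one sample per stratum per axis, strata permuted independently
    u = (rng.permuted(np.tile(np.arange(n), (4, 1)), axis=1).T + rng.uniform(size=(n, 4))) / n
    states = []
    for row in u:
        shift = 4.0 * np.round(row[1] * 16.0 / 4.0)
        states.append(
            PainState(
                gaba_scale=0.5 + 0.5 * row[0],
                e_inh_shift=float(np.clip(shift, 0.0, 16.0)),
                extra_nociceptor_fraction=0.5 * row[2],
                abeta_to_in_scale=0.5 + 0.5 * row[3],
            )
        )
    return states


def _two_gaussian(t_ms: np.ndarray, a1, b1, c1, a2, b2, c2) -> np.ndarray:
    return a1 * np.exp(-(((t_ms - b1) / c1) ** 2)) + a2 * np.exp(-(((t_ms - b2) / c2) ** 2))


@dataclass
class SyntheticUnit:
    """Ground-truth description of a synthetic extracellular unit."""

    unit_id: str
    cls: str  # "pEX" (monophasic) or "pIN" (biphasic)
    params: tuple  # (a1, b1, c1, a2, b2, c2), ms time base
    baseline_rate_hz: float
    modulation: dict = field(default_factory=dict)  # amplitude -> rate factor
    noise_sd: float = 0.0

    def clean_waveform(self, fs_hz: float = WAVEFORM_FS_HZ, dur_ms: float = WAVEFORM_DUR_MS):
        t = np.arange(0.0, dur_ms, 1e3 / fs_hz)
        return t, _two_gaussian(t, *self.params)


def random_unit_params(cls: str, rng: np.random.Generator) -> tuple:
    """Draw waveform parameters satisfying the class invariants."""
    a1 = -1.0  # dominant (negative) extracellular lobe
    b1 = rng.uniform(0.3, 0.45)
    c1 = rng.uniform(0.06, 0.12)
    b2 = b1 + rng.uniform(0.2, 0.45)
    c2 = rng.uniform(0.1, 0.25)
    if cls == "pEX":
        a2 = a1 * rng.uniform(0.0, 0.2)  # same-sign minor lobe: monophasic
    elif cls == "pIN":
        a2 = -a1 * rng.uniform(0.5, 1.1)  # opposite-sign lobe: biphasic
    else:
        raise ValueError("cls must be 'pEX' or 'pIN'")
    return (a1, b1, c1, a2, b2, c2)


def gen_unit_waveform(
    cls: str,
    params: tuple,
    noise_sd: float,
    seed: int,
    fs_hz: float = WAVEFORM_FS_HZ,
    dur_ms: float = WAVEFORM_DUR_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled mean waveform: two-Gaussian model plus white Gaussian noise."""
    a1, b1, c1, a2, b2, c2 = params
    if cls == "pEX" and a1 != 0 and abs(a2 / a1) >= 0.25 and np.sign(a2) != np.sign(a1):
        raise ValueError("pEX units must be monophasic (|a2/a1| < 0.25 for opposite-sign lobes)")
    if cls == "pIN" and a1 != 0 and a2 != 0 and np.sign(a2) == np.sign(a1):
        raise ValueError("pIN units must have opposite-sign lobes")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, dur_ms, 1e3 / fs_hz)
    v = _two_gaussian(t, *params)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=len(t))
    return t, v


@dataclass
class UnitRecording:
    """One unit's mean waveform plus baseline and per-condition spike trains."""

    unit_id: str
    waveform_t_ms: np.ndarray
    waveform: np.ndarray
    baseline_spikes_s: np.ndarray
    stim_spikes_s: dict  # condition key -> spike times (s, within the stim window)
    pulse_times_s: dict  # condition key -> stimulation pulse times
    stim_duration_s: float
    baseline_duration_s: float
    position: int | None = None


def save_session(recordings: list, units: list, out_dir) -> None:
    """Write a generated session as spike-time CSV plus a JSON truth sidecar.

    ``spikes.csv`` has columns ``unit_id,t_ms,epoch,condition``;
    ``waveforms.csv`` has ``unit_id,t_ms,v``; ``truth.json`` records each
    unit's class, modulation factors and stimulation pulse times for
    closed-loop tests.
    """
    import csv
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "spikes.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["unit_id", "t_ms", "epoch", "condition"])
        for r in recordings:
            for t in r.baseline_spikes_s:
                w.writerow([r.unit_id, f"{t * 1e3:.3f}", "baseline", ""])
            for cond, spikes in r.stim_spikes_s.items():
                for t in spikes:
                    w.writerow([r.unit_id, f"{t * 1e3:.3f}", "stim", cond])
    with open(out / "waveforms.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["unit_id", "t_ms", "v"])
        for r in recordings:
            for t, v in zip(r.waveform_t_ms, r.waveform):
                w.writerow([r.unit_id, f"{t:.5f}", f"{v:.6f}"])
    truth = {
        u.unit_id: {
            "class": u.cls,
            "baseline_rate_hz": u.baseline_rate_hz,
            "modulation": {str(k): v for k, v in u.modulation.items()},
            "params": list(u.params),
        }
        for u in units
    }
    pulses = {
        r.unit_id: {str(c): np.asarray(p).tolist() for c, p in r.pulse_times_s.items()}
        for r in recordings
    }
    (out / "truth.json").write_text(json.dumps({"units": truth, "pulse_times_s": pulses}))


def gen_recorded_session(
    units: list[SyntheticUnit],
    amplitudes,
    seed: int,
    baseline_s: float = 600.0,
    stim_s: float = 30.0,
    stim_frequency_hz: float = 90.0,
) -> list[UnitRecording]:
    """Emulate a recording session: baseline, then one stim block per amplitude.

    Spike trains are (piecewise-homogeneous) Poisson: the unit's baseline
    rate during baseline, ``rate × modulation[amp]`` during stimulation at
    each amplitude.  The default 10-minute baseline mirrors the
    spontaneous-activity recording that precedes stimulation blocks in the
    experimental protocol.  Pulse times are recorded per condition for
    artifact bookkeeping.
    """
    rng = np.random.default_rng(seed)
    out = []
    for unit in units:
        wf_rng = np.random.default_rng(rng.integers(2**31))
        t_ms, wf = gen_unit_waveform(
            unit.cls, unit.params, unit.noise_sd, seed=int(wf_rng.integers(2**31))
        )
        baseline = _poisson_train(unit.baseline_rate_hz, baseline_s, rng)
        stim, pulses = {}, {}
        for amp in amplitudes:
            factor = unit.modulation.get(amp, 1.0)
            stim[amp] = _poisson_train(unit.baseline_rate_hz * factor, stim_s, rng)
            pulses[amp] = np.arange(0.0, stim_s, 1.0 / stim_frequency_hz)
        out.append(
            UnitRecording(
                unit_id=unit.unit_id,
                waveform_t_ms=t_ms,
                waveform=wf,
                baseline_spikes_s=baseline,
                stim_spikes_s=stim,
                pulse_times_s=pulses,
                stim_duration_s=stim_s,
                baseline_duration_s=baseline_s,
            )
        )
    return out
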