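# scstim

Computational models and analysis tools for low-amplitude, low-frequency
(< 200 Hz) spinal cord stimulation (SCS) of the dorsal columns, and for the
dorsal-horn neural recordings used to study it.

Sub-perception SCS relieves neuropathic pain within seconds when amplitude,
frequency and spatial targeting are chosen carefully, but the circuit
mechanism is debated.  `scstim` implements an integrated in-silico pipeline
for the *surround inhibition* hypothesis: epidural stimulation sparsely and
irregularly activates large myelinated dorsal-column (DC) axons; those axons
are collaterals of Aβ afferents whose somatotopic origin (center vs surround
of the painful receptive field) is laid out mediolaterally/dorsoventrally in
the dorsal columns; and Aβ input from the *surround* drives inhibitory
interneurons that suppress the wide-dynamic-range (WDR) projection neuron of
the painful zone.

The package contains, as importable modules:

| module | contents |
| --- | --- |
| `scstim.stimulation` | biphasic pulse trains; analytic anisotropic volume conductor for a bipolar epidural paddle; field-table (HDF5) import |
| `scstim.mrg`, `scstim.dc_axon` | double-cable myelinated axon (MRG-type), activation thresholds by bisection, response libraries over (position × diameter × setting) grids, entrainment metrics |
| `scstim.dc_topography` | somatotopic DC maps: Z = X^0.15 + Y^0.45 position ranking, center/mix/surround zone wiring, truncated-normal diameter draws |
| `scstim.dh_network` | three-node center/surround dorsal-horn circuit (EX/IN/WDR per node, 15 Aβ + 15 Aδ + 3 C inputs per node), conductance-based, with neuropathic pain-state axes |
| `scstim.synthetic_data` | pain-input spike trains (2.2 Hz A / 1.5 Hz C, episodic bursting), Latin-hypercube pain states, extracellular unit waveforms, emulated recording sessions |
| `scstim.spike_analysis` | PSTH bin-width optimization, z-score responder detection, ±1 response normalization, fuzzy c-means clustering, two-Gaussian waveform fits and pEX/pIN classification |
| `scstim.experiments` | end-to-end amplitude sweeps, frequency/pulse-width grids, pain-state sweeps, onset timecourses |

All inputs are generated; nothing is downloaded.  Amplitudes are expressed
as % of the model motor threshold (MT = 100 µA); the perception threshold
(PT) is estimated as 50% of MT.

## Worked example

Simulate one dorsal-column map under surround-targeted 90 Hz / 225 µs
stimulation at 40% MT and score the zone-1 WDR neuron:

```python
from scstim.experiments import ExperimentConfig, LibraryCache, run_single_trial

cfg = ExperimentConfig()            # desk-scale protocol: 6 s, stim on final 3 s
cache = LibraryCache(cfg)
trial = run_single_trial(cfg, cache, map_seed=0, targeting="surround",
                         freq=90.0, pw=225.0, amplitude_pct_mt=40.0)
print(f"baseline {trial['baseline_hz']:.1f} Hz, "
      f"stim {trial['stim_hz']:.1f} Hz, "
      f"raw change {trial['raw_delta_hz']:+.1f} Hz, "
      f"normalized {trial['normalized_delta']:+.2f}")
```

```
baseline 54.0 Hz, stim 7.7 Hz, raw change -46.3 Hz, normalized -0.86
```

The WDR neuron of the painful (center) zone drops to a fraction of its
pain-state baseline: the stimulated fibers all project to the *surround*
zone, whose interneurons inhibit the center WDR neuron.  Sweeping amplitude
shows the signature nonmonotonic profile — little effect at 20% MT (few
axons recruited), maximal median suppression at 40% MT, and progressively
less suppression above PT as center-zone axons are recruited and excite the
WDR neuron directly.

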