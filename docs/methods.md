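# Methods

This note documents the models, the numerical choices and the calibration
behind `scstim`, in the package's own terms. Units: mV, ms, nF, µS, nA
internally; user-facing amplitudes in µA or % of motor threshold (MT).

## Extracellular field

The bipolar epidural paddle (two 1 × 2 mm platinum contacts, 2 mm
center-to-center along the cord axis) is collapsed to two point sources —
cathode −I, anode +I — in a homogeneous anisotropic medium with
longitudinal conductivity σ_L = 0.6 S/m along the fiber axis (z) and
transverse conductivity σ_T = 0.083 S/m, typical white-matter values. The
potential of a point source is

    V(x, y, z) = I / (4π √(σ_T σ_L (x² + y²) + σ_T² z²))

and the bipolar field is the superposition of the two sources, linear in
the injected current. Two calibration parameters absorb what a full
finite-element model would supply:

* `dorsoventral_offset` (default 0.2 mm) — the epidural gap between the
  contacts and the cord surface; the rat epidural space is thin.
* `dorsal_insulation_factor` (default 3.0) — a lumped boundary factor: the
  paddle's insulating dorsal backing acts as an image source (×2), and the
  surrounding vertebral canal confines current toward the cord. The
  default was set so that the dorsomedial fiber population is recruited
  over roughly 20–100 µA with the model MT fixed at 100 µA, and so that
  recruitment of the most-dorsomedial versus the second tier of fibers is
  best differentiated at 40–50% MT. This calibration was fixed at the
  fiber level before any network simulations were examined.

Users with genuine finite-element exports can bypass the analytic field
entirely via `load_field_table` (HDF5 grid of mV/µA, trilinear
interpolation).

Stimulation pulses are symmetric, biphasic and rectangular (cathodic phase
first, no interphase gap), charge-balanced by construction.

## Dorsal-column axon

Fibers are double-cable myelinated axons of the McIntyre–Richardson–Grill
(MRG) type: ≥21 nodes of Ranvier carrying fast Na⁺ (m³h), persistent Na⁺
(p³), slow K⁺ (s) and leak conductances (3.0, 0.01, 0.08, 0.007 S/cm²;
E_Na 50, E_K −90, E_leak −90 mV; rest −80 mV), separated by internodes of
2 myelin-attachment (MYSA), 2 paranode (FLUT) and 6 internode (STIN)
sections with passive axolemma and a myelin sheath forming the second
cable. Geometry follows the published MRG diameter table; dorsal-column
fibers (2.2–8 µm) fall mostly below the table's smallest entry (5.7 µm),
so each geometric parameter is linearly extrapolated versus fiber diameter
and floored at physical minima (axon diameter ≥ 1 µm, node diameter
≥ 0.7 µm, lamellae ≥ 30, internode length ≥ 50·D). Internode length
remains strictly increasing in diameter.

The two Kirchhoff equations per compartment (transaxolemmal voltage and
periaxonal potential) are integrated with Crank–Nicolson at dt =
0.0125 ms; gate variables use staggered Rush–Larsen updates with
tabulated rate functions. The block-tridiagonal system (2×2 blocks) is
solved by block Thomas elimination each step. Spikes are upward crossings
of −20 mV at the most rostral node (mirroring a cervical confirmation
recording) with a 1 ms lockout.

The activation threshold (AT) of a fiber is defined on a *single*
symmetric biphasic pulse of the train's pulse width, bracketed in
[1, 1000] µA and bisected to 1% — a train-independent normalization axis.
Near threshold (100–110% AT) trains at 90 Hz evoke irregular,
intermittent firing (the slow K⁺ afterhyperpolarization raises threshold
for ~tens of ms after each spike); by 120–140% AT axons follow 1:1. Both
regimes are emergent, not imposed.

Response libraries tabulate spike trains over (position × diameter ×
frequency × pulse width × amplitude). Two exact shortcuts keep libraries
desk-scale: amplitudes below 95% of the fiber's AT are recorded silent
without simulation (no subthreshold facilitation exists across ≥5 ms
periods — verified by the train-versus-pulse consistency property), and a
fiber that follows every pulse of a 1-s probe 1:1 with stationary latency
has reached its periodic steady state, so longer trains are continued
periodically (frequencies ≤ 200 Hz only; any deviation from strict 1:1
falls back to full simulation).

## Dorsal-column somatotopy

Fiber positions live on a 10 × 6 mediolateral × dorsoventral lattice
spanning one half of the rat dorsal columns (ML 0.05–0.9 mm from the
midline, DV 0.06–0.45 mm below the surface). Positions are ranked by
Z = X^0.15 + Y^0.45, where X and Y are normalized ranks in [0, 1]
(0 = most medial, most dorsal); the 20 lowest-Z positions form tier 1,
then tiers 2 and 3. One stated coordinate ambiguity is resolved rather
than hidden: the ranking text calls Y "rostral-caudal" while selecting
"most medial and dorsal" positions; Y is implemented as dorsoventral
depth.

A sampled map draws 15 of 20 positions per tier without replacement and
assigns diameters from a truncated normal on [2.2, 8] µm whose
*post-truncation* mean and SD are exactly 4.4 and 1.0 µm (the underlying
normal is moment-matched at loc 4.3447, scale 1.0622; plain truncation of
N(4.4, 1) would bias the mean by +0.038 µm). Zone wiring by targeting:
center (tier 1→zone 1, 2→2, 3→3), surround (tier 1→zone 2, tier 2→zone 1,
tier 3→zone 3), mix (tier 1 split 8/7 between zones 1 and 2, tier 2 the
complement). Library lookups use the nearest simulated diameter.

## Dorsal-horn network

Three nodes (zones), each with one excitatory interneuron (EX), one
inhibitory interneuron (IN) and one wide-dynamic-range projection neuron
(WDR), four compartments each (dendrite, soma, hillock, axon) with the
published compartment dimensions. Each node has 15 Aβ, 15 Aδ and 3 C
afferent slots. The synapse table (conductances in nS; AMPA/NMDA/NK1/
GABA_A/Glycine double-exponential kinetics with the stated τ₁/τ₂/E_syn)
is instantiated exactly, including the reciprocal cross-node projections
(IN→EX GABA_A 3.66; IN→WDR GABA_A 4.5 + glycine 4.5; EX→WDR NMDA 0.014 +
AMPA 0.14, each for every ordered node pair). Every synapse is peak-
normalized: a single event reaches exactly g_max. NMDA carries a
sigmoidal Mg²⁺ block (half-block −20 mV, slope 8 mV). Dorsal-column
responses enter by merging into the Aβ slots of their zone.

The ionic inventory of the circuit's source models is not published, so
channels are Hodgkin–Huxley-type Na⁺/K_DR/leak (Traub–Miles kinetics,
0.10/0.08 S/cm² on soma, hillock and axon; leak 1e-4 S/cm², E_leak
−67 mV) plus an A-type K⁺ current on the IN soma (0.04 S/cm²) and a slow
Ca²⁺ current with a Ca-activated nonspecific cation current on the WDR
soma (0.002 / 0.0003 S/cm²) supporting wind-up. All densities are
config-exposed; the behavioral contracts below are the acceptance
surface. Integration: per-neuron tridiagonal Crank–Nicolson at
0.0125 ms; soma spikes at −20 mV with 2 ms lockout; 1 ms synaptic delay.
Afferent synapse states are warm-started at their stationary means for
the slot's baseline rate, removing slow-receptor (NK1, τ₂ = 3 s)
equilibration transients.

Two deliberate departures from a naive reduction:

* **Synapse placement and cable filtering.** All synapses are dendritic,
  and the dendrite-to-soma coupling uses elevated effective axial
  resistivities (600 Ω·cm for EX/IN, 1200 Ω·cm for WDR). Collapsing an
  extended dendritic tree into one cylinder otherwise removes the cable
  attenuation of fast transients: every 24-nS Aβ EPSP would force a soma
  spike, making the WDR a relay rather than an integrator, and
  perisomatic inhibition would hold an absolute veto. With filtering, the
  WDR sums its inputs, sparse irregular Aβ input yields *net inhibition*
  (the interneuron pathway wins), and high-rate input yields net
  excitation (direct drive wins) — the balance at the core of the model.
* **Stimulus-driven interneurons.** At this operating point the
  interneurons are nearly silent at rest and engage through temporal
  summation of afferent events (they follow 90-Hz input vigorously,
  ≤30-Hz input barely). Consequences: the inhibition-knockout check is
  run as a bicuculline analog (conductances zeroed during surround
  drive), and the peripheral recruitment validation uses a 50-Hz test
  stimulus — the rate used for motor-threshold testing experimentally.

Pain states scale GABA_A conductance (0.5–1), shift GABA_A/glycine
reversal potentials (+0–16 mV in 4-mV steps), activate up to 50% more
Aδ/C fibers in surround nodes (idle slots first, then duplicated
activity) and scale Aβ→IN conductance (0.5–1); 30 states are drawn by
4-axis Latin hypercube sampling. Because the interneurons are
stimulus-driven, disinhibition does not raise the resting baseline here,
and the suppression optimum does not shift to higher amplitudes under
the (gaba 0.5, shift 16 mV) state — a known limitation of this operating
point, documented rather than patched.

## Synthetic inputs

* **Pain afferents.** Per-fiber rates are Gamma(shape 2) with population
  means 2.2 Hz (A) and 1.5 Hz (C); non-bursting trains are Poisson. One
  third of A-fibers burst *episodically*: within an episode, bursts have
  exponential intra-burst ISIs (mean 30 ms), Poisson sizes (mean 6,
  min 2) and exponential inter-burst gaps (mean 551 ms); episodes contain
  Poisson-many bursts (mean 7) and are separated by quiescent intervals
  sized so each fiber's long-run rate equals its drawn target. Sustained
  bursting at the stated parameters would imply ≈8.6 Hz — incompatible
  with the 2.2 Hz population mean — so episodic alternation is the only
  structure under which all stated statistics hold simultaneously. The
  episodes impart slow (∼5 s) rate fluctuations to the network, which
  dominate the trial-to-trial variance of WDR rate changes.
* **Unit waveforms.** Mean extracellular waveforms are a sum of two
  Gaussians a₁·exp(−((x−b₁)/c₁)²) + a₂·exp(−((x−b₂)/c₂)²) sampled at
  40 kHz over 1.2 ms; monophasic (pEX-like) units have a same-sign minor
  lobe (|a₂/a₁| < 0.25), biphasic (pIN-like) units opposite-sign lobes.
* **Recorded sessions.** Piecewise-homogeneous Poisson trains: 600 s of
  baseline (mirroring the ≥10-min spontaneous recordings of the
  experimental protocol), then a 30-s stimulation block per amplitude at
  the unit's rate × a known modulation factor, with pulse times recorded.

What the generators do *not* emulate: overlapping spikes and sorting
errors, non-Poisson spike-train structure in the recorded units, electrode
drift, and genuinely coupled modulation across amplitudes — so closed-loop
test results bound the pipeline's statistical behavior under its own
assumptions, not its robustness to real-recording pathologies.

## Analysis pipeline

* **Bin width**: the shift-averaged spike-count cost
  C(Δ) = (2·mean(k) − var(k))/Δ², averaged over 8 bin-grid offsets,
  minimized over a candidate grid spanning 10–2000 ms; trains with < 2
  spikes fall back to 500 ms with a warning.
* **Responders**: stimulation bin counts are z-scored against the mean
  and SD of baseline bin counts at the same width (Poisson σ = √µ
  fallback for degenerate variance, flagged); a unit is a responder when
  ≥3 consecutive bins have |z| ≥ 1.96; direction is the sign of the
  summed significant z. Artifact handling imposes the same per-pulse
  dead-time pattern (default 1 ms) on the stimulation train and,
  phase-matched, on the whole baseline; sessions without artifacts are
  analysed with blanking off, since the correction costs power through
  the discreteness of the Poisson threshold.
* **Normalization / inclusion**: per-amplitude Δrates are scaled so the
  largest |change| is ±1; clustering includes units with baseline
  ≥ 1.5 Hz responding at ≥1 amplitude.
* **Clustering**: covariance PCA of the normalized unit × amplitude
  matrix to two components (responses are already on a common ±1 scale),
  then fuzzy c-means (fuzzifier 2.0, ≤500 iterations, objective tolerance
  1e-5, 10 seeded restarts) for k = 2–6, with silhouette and
  Davies–Bouldin optima reported on hard labels.
* **Waveform classification**: multi-start least squares of the
  two-Gaussian model (opposite-extrema, same-sign-minor-lobe and
  residual-seeded starts); overlapping same-sign Gaussians are collapsed
  to one lobe before feature extraction (amplitude ratio, signed ratio,
  lobe widths, inter-lobe interval). A quadratic Gaussian discriminant
  trained on the generator's class-conditional distributions (SNR drawn
  6–30 per training unit) assigns pEX/pIN only above 60% posterior. The
  discriminant is an sklearn estimator and can be retrained or
  serialized.

## Experiment scales

The default protocol is desk-scale: 6 s simulated per run with
stimulation over the final 3 s and the first second excluded from the
baseline window; `full_scale=True` restores 18 s / 10 s. The headline
comparison (surround-targeted 90 Hz / 225 µs over {20, 30, 40, 50, 60,
80}% MT) uses 15 map seeds in `scripts/acceptance.py` and 10 in the test
suite; the reported optimum is the amplitude of the most negative median
raw rate change. Default frequency/pulse-width grid:
{30/450, 50/300, 90/225, 90/275, 130/210, 150/200, 200/200}
(approximately charge-matched); the four named settings are fixed, the
rest configurable.

## Known limitations

* The analytic field reproduces threshold gradients, not absolute
  FEM-grade potentials; the insulation factor is a calibrated stand-in.
* One neuron per class per node: population heterogeneity, laminar
  structure and descending modulation are out of scope.
* Kilohertz settings are accepted as configuration but conduction-block
  physics at 10 kHz is not validated.
* The disinhibition-shift behavior discussed above.
* Axon trajectories are straight; no collateral branching into the horn.
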