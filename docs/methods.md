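# Methods

`acprecess` implements the computational chain needed to study how weak
alternating-current (AC) stimulation entrains cortical spiking and
gradually shifts its preferred phase (phase precession): circular
entrainment statistics, extracellular spike extraction, a sliding-window
precession classifier, a macroscale motor-evoked-potential (MEP)
phase-drift analysis, and a conductance-based three-neuron motor-cortex
microcircuit with uniform-field coupling and synaptic-weight sweeps.

## Phase conventions

One convention is used everywhere: 0° is the stimulation peak, 180° the
trough, and angles increase counter-clockwise (a positive shift means
spiking moves later in the cycle). The stimulation waveform is a cosine,
so an ideal reference assigns a spike at time *t* the phase
360°·frac(f·(t−t₀)). Physically, 0° corresponds to the AC phase whose
field direction depolarizes the somata of posterior-bank (primary motor,
BA4) pyramidal cells; 180° depolarizes anterior-bank (premotor, BA6)
somata. Internally phases are radians in [0, 2π); all interfaces speak
degrees.

## Circular statistics

* **PLV** — magnitude of the mean unit phase vector, |Σₖ e^{iθₖ}|/N;
  0 = no locking, 1 = perfect locking.
* **Preferred phase** — the circular (resultant-vector) mean; an
  arithmetic mean is ill-defined on the circle. A zero resultant
  (antipodal or uniform samples) is reported through an explicit
  `phase_defined` flag, never as a silent 0 or bare NaN.
* **Rayleigh test** — p = exp(√(1+4n+4(n²−Rₙ²)) − (1+2n)) with
  Rₙ = n·PLV, the standard small-sample-corrected approximation.
* **Circular–linear correlation** —
  r = √((r²_cx + r²_sx − 2 r_cx r_sx r_cs)/(1 − r²_cs)) from the three
  Pearson correlations of cos θ, sin θ and the covariate, with p from
  χ²(2) on n·r². Degenerate inputs (constant covariate or constant
  phase) raise instead of returning a meaningless number.
* **Angular difference** — minimal signed rotation in (−180°, 180°],
  the 180° tie broken positive.

The test suite cross-checks all of these against an independent
implementation (pingouin) and against brute-force compositions.

## Spike preprocessing

Continuous recordings are stored as raw little-endian float32 plus a
JSON sidecar with the sampling rate. The pipeline is:

1. **Spectral interpolation** of narrow-band stimulation artifacts: the
   rfft amplitude inside each target band (default half-width 0.5 Hz) is
   replaced by linear interpolation of the mean amplitudes in equally
   wide flanking bands; phases are preserved so the inverse transform is
   real and length-preserving.
2. **Band-pass** 300–3000 Hz, 4th-order Butterworth, applied
   forward–backward (zero phase) so spike times are not biased.
3. **Robust noise estimate** σₙ = median(|x|)/0.6745, insensitive to
   the spikes themselves (an ordinary SD inflates by an order of
   magnitude on spiky traces).
4. **Detection** at threshold λ·σₙ (default λ = 4) on |x|, i.e. both
   polarities; each crossing is aligned to the local extremum and a
   32-sample snippet (8 before, 24 after the peak) is stored. A 1 ms
   censor window prevents double detection; snippets that would extend
   past the trace ends are dropped and counted.
5. **Cluster SNR** = mean over spikes of (max(sᵢ)−min(sᵢ))/(2·std(εᵢ)),
   εᵢ = sᵢ − s̄, with the sample standard deviation over snippet
   samples.

Note that a 4σ threshold on band-limited Gaussian noise has an
irreducible false-detection rate (the Rice crossing rate, ≈ 2·T·ν₀·e^{−8}
events for a flat 300–3000 Hz band); the tests bound noise-only
detections by that quantity rather than pretending it is zero.

## Precession classification

Spikes are assigned phases against an ideal sinusoid or against the
band-passed LFP's analytic phase (2nd-order Butterworth at the block
frequency ± 1 Hz, Hilbert transform; the analytic angle is 0 at the
oscillation peak, matching the package convention). Ramp periods
(default 10 s) are excluded from phase assignment.

A sliding-window track (canonically 132 s windows, 12 s steps, 20
windows, tiling one 6-minute block; spikes pooled across blocks at
matched window index) records PLV, preferred phase and Rayleigh p per
window. Windows with fewer than 10 spikes are non-responsive. The
classifier then applies three steps:

1. *Responsiveness*: at least max(10, 50% of windows) windows with
   Rayleigh p < 0.05, else **non-responsive**.
2. *Consistency*: circular–linear correlation of preferred phase
   against window index over responsive windows with r > 0.5 and
   p < 0.05, else **non-uniform** (a near-constant track short-circuits
   to **stable**).
3. *Magnitude*: total shift — the cumulative unwrapped angular
   difference from the first to the last responsive window, so drifts
   through 360° are not aliased — must exceed 15°, else **stable**;
   its sign gives **clockwise** (negative) or **counter-clockwise**.

Because the windows average over their 132 s span, a linear drift
planted over a whole block is observed attenuated by the ratio of the
first-to-last window-center span to the block length (228/360); the
fixtures used in testing plant drifts in window-center units.

## MEP phase-drift analysis

Trials carry (trial index, block, probed phase ∈ {0°, 90°, 180°, 270°},
amplitude). Amplitudes are normalized by the block mean (removing block
gain and the between-block reset). The four per-phase means are
condensed into a polar excitability vector x = M(180°)−M(0°),
y = M(270°)−M(90°), whose direction (pure +x → 180°, pure +y → 270°,
i.e. atan2(−y, −x)) equals the amplitude-weighted circular mean of the
phase means — for M(φ) = 1 + d·cos(φ−μ) it returns exactly μ.

The windowed track uses 55-trial windows stepped by 5 trials (20
windows over a 150-trial block), with the per-block (x, y) vectors
averaged componentwise across blocks. Drift is quantified by the
circular–linear correlation of window phase against window index, and
the overall excitability trend by a Pearson correlation of normalized
amplitude against within-block trial index.

**Permutation null.** Because consecutive windows share 50 of 55
trials, even phase-shuffled data produce smooth pseudo-trajectories and
the analytic circular–linear p is anticonservative. The package
therefore shuffles phase labels within block (amplitudes and order
preserved), recomputes the full windowed track and drift correlation
per permutation, and reports p = fraction of null r ≥ observed r. At
low modulation depth (7%) and realistic multiplicative noise this test
has limited power — a real limitation of heavily overlapping windows,
not an implementation artifact — while the windowed track still
recovers planted drift endpoints to within ~14° (median).

## Microcircuit model

Three two-compartment neurons: a premotor pyramidal cell (BA6_PY), a
primary-motor pyramidal cell (BA4_PY) and a fast-spiking interneuron
(IN). BA6_PY's somatodendritic axis is anti-parallel to BA4_PY's and
IN's, so a uniform field polarizes the two pyramidal cells with
opposite sign at every instant.

* **Compartments** — cylindrical soma (30×30 µm, pyramidal) and
  dendrite (500×3 µm) joined by a lumped axial conductance (8 nS);
  C_m = 1.5 µF/cm². The interneuron is smaller (25×25 µm soma, 300 µm
  dendrite).
* **Channels** (rate functions collected in
  `acprecess/microcircuit/channels.py`) — pyramidal soma: fast Na,
  delayed-rectifier K, slow non-inactivating K (M-current), leak,
  high-threshold Ca and Ca-dependent K with a first-order calcium
  pool; interneuron: Na, Kv and leak only (fast spiking). Rates follow
  the standard minimal Hodgkin–Huxley formulations for regular-spiking
  and fast-spiking cortical cells with an adjustable threshold
  parameter V_T = −55 mV.
* **Synapses** — dual-exponential conductances normalized so the peak
  equals the weight; AMPA (0.5/5 ms), NMDA (2/26 ms, with the standard
  sigmoidal Mg²⁺ unblock at 1 mM, toggleable), GABA_A (0.5/15 ms,
  E = −80 mV). Excitatory synapses target the dendrite, the inhibitory
  synapse the soma. Connectivity: BA6→BA4 (AMPA+NMDA, 2 ms delay),
  BA6→IN (AMPA+NMDA, 2 ms), BA4→IN (AMPA, 1 ms), IN→BA4 (GABA_A,
  1 ms). Every neuron receives an excitatory Poisson background synapse
  (E = 0 mV, 2/10 ms).
* **Field coupling** — for a uniform field E(t), the extracellular
  potential is V_e = −E(t)·r; the membrane equation receives the field
  through the extracellular-potential difference across the
  soma–dendrite axis, ΔV_e = −E(t)·axis·L, entering the axial coupling
  current. 3 V/m along a 500 µm axis gives a 1.5 mV peak extracellular
  potential difference. The temporal waveform is
  amplitude·envelope·cos(2πf(t−t_on)) with linear on/off ramps
  (default 10 s).
* **Integration** — exponential Euler for gating variables and a
  semi-implicit update for voltages (implicit in the compartment's own
  voltage, explicit in its neighbor's), dt = 0.025 ms, in a
  numba-compiled kernel. Spikes are upward 0 mV crossings at the soma
  with a 1 ms refractory. Identical (config, seed) reproduce identical
  spike trains; halving dt changes 30-s spike counts by < 2%; the
  passive two-compartment response to a sinusoidal field matches the
  closed-form RC phasor solution within 5%.

### Calibration and what it reproduces

All morphology and weight constants are package defaults, fully exposed
in `build_default_circuit` and echoed next to every result. The
"alpha" condition tunes the pyramidal Poisson drive (5000 Hz, weights
≈ 3.7–4.6·10⁻⁵ µS) for ~10 spikes/s baseline firing; "beta" for ~17
spikes/s, with the BA6→IN NMDA weight reduced so the interneuron rate
stays comparable across conditions.

Two calibration choices matter for phases. First, pyramidal cells
operate in a mean-driven regime with a relatively fast M-current
(τ_max = 100 ms, g = 0.15 mS/cm²): spike-frequency adaptation makes the
entrained firing-rate response *lead* the somatic polarization, so at
10 Hz BA6 fires around 140° (within the 90–180° depolarizing
half-cycle) and BA4 around −40–0°, matching the spatial pattern
expected from the anti-parallel geometry. Second, the feed-forward
inhibition (BA6→IN→BA4) sculpts BA4's firing window: with the default
weights the alpha-condition BA4 cell prefers ≈ 90° at the base NMDA
weight, and systematically increasing the BA6→BA4 NMDA weight (20
trials, constant increment equal to the base weight) pulls the
preferred phase counter-clockwise to ≈ 140–150° — a monotone trajectory
(Spearman ρ ≈ 0.99) reproducing the plasticity-driven precession the
model is meant to capture. By default all sweep trials share one
Poisson realization so the trajectory isolates the weight effect;
independently seeded trials are available.

Two behaviors of the target phenomenology are **not** reproduced by
this calibration and are reported honestly by the acceptance machinery:

* In the beta condition (20 Hz) the membrane and synaptic lags roughly
  double in phase units; BA4's entrained phase sits near 310° and the
  premotor NMDA drive arrives ~100° later still, so the weight sweep
  barely moves the preferred phase (≈ 310°→313°) instead of traversing
  ~100°→180°. Extensive exploration (adaptation strength and speed,
  membrane speed, axial coupling, interneuron kinetics and drive
  composition, detuning) showed that calibrations fixing beta break
  alpha: the locked-phase responses move in opposite directions with
  adaptation at the two frequencies in this two-compartment model.
* The inhibitory control sweep (same absolute increments applied to the
  IN→BA4 GABA_A weight) shifts BA4's phase by ≈ +35° rather than < 10°:
  in this calibration the inhibition timing is precisely the mechanism
  that positions the trial-1 phase, so it cannot simultaneously be
  phase-neutral. Operating at the deep-inhibition fixed point makes
  GABA_A phase-neutral but removes the NMDA sweep's leverage.

### Problem sizes

The package defaults to the experimental protocol (6 min baseline +
6 min stimulation). The shipped tests and the acceptance script use
scaled-down spans — 60 s baselines for rate measurements and 70–130 s
stimulation per sweep trial — which this package treats as its standard
desk-scale problem sizes; phase estimates at these spans are stable to
roughly ±5–10° across seeds.

## Synthetic data generators

Three seeded generators provide (data, ground-truth) pairs:

* **Spike trains** — a homogeneous Poisson count of spikes scattered
  over the duration; each spike keeps its cycle but its within-cycle
  position is redrawn from von Mises(μ(t), κ) with μ(t) drifting
  linearly, so phase structure is controlled exactly while the rate
  stays flat (rate-independent precession, matching the observation
  that stimulation does not change firing rates). κ = 0 gives uniform
  phases.
* **Extracellular traces** — Gaussian noise plus biphasic spike
  templates placed with a minimum gap, plus an optional sinusoidal
  stimulation artifact; injection times are the truth.
* **MEP series** — amplitude = base·(1 + depth·cos(φ−μ))·lognormal(cv)·
  (1 + trend·block-fraction), with μ drifting linearly within each
  block (phase resets between blocks, matching the windowing's
  across-block averaging) and the four phase labels allocated evenly in
  shuffled order. The lognormal noise (default cv = 0.25) keeps
  amplitudes positive and right-skewed; mean 1 by construction.

What the generators deliberately do not emulate: bursting and
refractory structure in spike trains, electrode drift and multi-unit
overlap in traces, and serial correlation or fatigue effects in MEP
amplitudes. Passing tests therefore demonstrate correctness of the
analysis chain under the stated statistical models, not robustness to
every artifact of real recordings.

## Known limitations

* The microcircuit is a minimal three-cell caricature: one neuron per
  population, no short-term synaptic dynamics, no morphological detail;
  its constants are behavioral calibrations, not measured biophysics.
* The beta-condition sweep phases and the inhibitory-control
  phase-neutrality are not reproduced (see above).
* The permutation drift test is honest but low-powered at small
  modulation depths because of the 91% window overlap.
* Spike sorting proper (waveform clustering) is out of scope; the
  preprocessing stops at detected, aligned snippets plus a cluster SNR.
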