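# Model and analysis methods

`msping` simulates a patch of early visual cortex as a microsaccade (MS)
modulated excitatory–inhibitory spiking network and reconstructs, from the
simulated data alone, the event-locked synchronization and
information-transfer phenomenology: a broadband, stimulus-insensitive
transient after each MS followed by narrow-band sustained gamma whose
locking is selective for distance, connectivity and input similarity, and
whose phase structure gates feedforward transmission to a downstream
population.

## Network model

**Neurons.** Izhikevich two-variable neurons with exponential synapses:

    dV/dt = 0.04 V² + 5 V + 140 − u + I(t)
    du/dt = a (b V − u)
    ds/dt = −s / τ_syn

with reset `V ← c`, `u ← u + d`, `s ← 1` when `V ≥ 30 mV`. Regular-spiking
(RS) excitatory cells use (a, b, c, d) = (0.02, 0.2, −65, 8) with an
AMPA-type synapse (τ_syn = 10 ms, V_rev = +50 mV); fast-spiking (FS)
inhibitory cells use (0.1, 0.2, −65, 2) with a GABA-A-type synapse
(τ_syn = 5 ms, V_rev = −90 mV). The total input to neuron *i* is
`Σ_j s_j g_ij (V_rev,j − V_i) + I_imp,i(t) + η(t)`.

**Integration.** Classical 4th-order Runge–Kutta at dt = 0.5 ms. Spike
detection happens after a completed step; a spiking neuron's gate update
(`s ← 1`) becomes visible to its targets on the next step, i.e. a one-step
synaptic latency and no axonal delays. The noise current η is sampled once
per step per neuron from N(0, σ²) with σ = √(max(I_imp, 0)/SNR) and applied
to V after the deterministic update. The alternative reading
σ = √I_imp / SNR is available as `NoiseSpec(variant="amplitude")`. SNR = 2
throughout.

**Geometry and wiring.** 1600 RS cells on a 40 × 40 grid (spacing 1, the
distance unit) and 400 FS cells on a 20 × 20 grid spanning the same extent,
both with periodic boundaries (a torus). Each receiver draws exactly N_S
senders, with replacement, with probability ∝ exp(−D²/2σ_S²) (toroidal D,
self excluded); repeated draws accumulate integer multiples of the unit
weight g_S, so total incoming weight is exactly N_S·g_S per projection.
Defaults (see "Calibration" below):

| projection | N_S | g_S   | σ_S      |
|-----------|-----|-------|----------|
| E→E       | 40  | 0.006 | √20 ≈ 4.47 |
| E→I       | 40  | 0.012 | √20      |
| I→E       | 20  | 0.04  | 1        |
| I→I       | 10  | 0.02  | 1        |

Excitatory wiring reaches several times further than inhibitory wiring.
The excitatory reach is interpreted as a Gaussian *variance* of 20 squared
grid units. Under the alternative reading (σ = 20 on a 40-torus) the
coupling between the nearest and the most distant sites differs by only a
factor e⁻¹, and we verified over a broad synaptic-strength grid that the
network is then either globally locked or globally unlocked — the
distance-selective sustained gamma that the model exists to produce cannot
arise. The variance reading leaves the inhibitory value (1) unchanged and
yields a gamma coherence length of a few electrode spacings, matching the
local phase-locking footprints the model is meant to show.

**Anisotropic variant.** For the connectivity-anisotropy experiment all
E→E connections are removed except those emerging from the centre neuron,
which are redrawn from an oriented anisotropic Gaussian footprint
(σ_long = 10, σ_short = 2 — a calibration choice) with strength scaled ×3.

**Two-area variant.** A downstream population (100 RS + 25 FS, no spatial
geometry, no feedback to the input layer) receives convergent feedforward
input: each downstream neuron draws 40 senders from an isotropic Gaussian
(σ = 6) over the V1 E sheet centred on the shared receptive-field centre
(the grid centre), with unit weight 0.015 to E cells and half that to I
cells; local wiring is drawn uniformly. These values were calibrated so
the downstream E cells fire at 15–20 Hz from feedforward drive alone (they
receive no imposed current, hence also no imposed-current noise).

## Drive

The imposed current factorises as `I_imp,i(t) = J_i · ς(t)`.

**MS modulation ς(t).** A T-periodic impulse train (T = 400 ms) convolved
with a biphasic kernel: a presaccadic suppression lobe for t < 0
(τ₁ = 15 ms, τ₂ = 10 ms, depth M_N = 0.2) and a postsaccadic transient for
t ≥ 0 (τ₁ = 100 ms, τ₂ = 40 ms, strength M_P = 0.5). Each
difference-of-exponentials lobe is divided by its own peak value, so
K(0) = 1, max K = 1.5 (at ≈ 61 ms), min K = 0.8, and K → 1 away from the
saccade. The printed closed-form normaliser with swapped-sign denominators
does not peak-normalise (it evaluates to ≈ 2.76 instead of ≈ 0.326 for the
default constants) and is kept only as `normalization="printed"`. The
series is realised as a baseline of 1 plus shifted (K − 1) lobes, which
keeps the baseline exactly 1 for any T; lengthening T shifts onsets without
changing the post-onset lobe.

**Spatial patterns J.**
* *Smoothed noise* (network-characterisation runs): Gaussian white noise on
  the torus, low-pass filtered with a periodic Gaussian of scale 4 grid
  units, min-max normalised and scaled to J_E ∈ [0, 6]; I cells receive
  half the E drive sampled on their grid. Gain and smoothing scale are
  calibration outcomes: coarser smoothing weakens nearby-pair input
  contrast, and the gain sets how strongly input differences detune local
  gamma (see "Calibration").
* *Oriented bars*: a Heaviside-thresholded product of cosines (orientation
  selected by which axis carries the doubled spatial frequency), plus a
  low-amplitude oriented sinusoid whose exact form is a free choice (the
  printed expression is typographically corrupted); drive spans 0.3–1 of
  the gain so off-bar cells stay weakly active.
* *Image patches*: luminance min-max normalised to [0, 1], ×7 for E cells
  and ×3.5 for I cells (sampled at every second pixel). A constant patch is
  mapped to mid-level 0.5 with a warning.
* *Synthetic natural patches*: a random field with power-law spectrum
  f^(−2), partially posterized into 5 quantile levels (85 % mixing). The
  posterization emulates the piecewise-homogeneous luminance regions
  (surfaces bounded by occlusion edges) of natural photographs; those
  near-homogeneous regions — not the spectral slope per se — are what the
  feedforward experiments exploit, because equal drive means zero detuning
  and hence coherent local assemblies. The radially averaged log-power
  slope stays within ≈ 0.15 of −2. What the generator does *not* emulate:
  oriented structure, phase congruency across scales, luminance–contrast
  statistics of real scenes; results on real photographs may differ in
  degree.

## LFP and spectral analysis

**LFP.** Each of 10 × 10 virtual electrodes (spacing 4 grid units) sums
excitatory membrane potentials with Gaussian weights exp(−D²/2), σ = 1 grid
unit, toroidal D, truncated at 5σ. Weights are deliberately not
normalised; every downstream measure is scale invariant.

**Event-locked spectra.** Epochs span −50 to +400 ms around each MS onset
(the first interval of every run is discarded). Sliding Hann windows
(150 ms for spectra and time–frequency power, 50 ms for time-resolved
maps), zero-padded to 1024 samples (fs = 2 kHz, Δf ≈ 1.95 Hz), hop 10 ms.
Each window segment is linearly detrended before tapering: the MS-evoked
depolarisation is large and slow, and without detrending its leakage
through the Hann mainlobe saturates the phase-locking value at 1 for every
pair up to ≈ 30 Hz (50-ms window), masking the oscillatory band. An
evoked-subtraction variant (removing the across-saccade mean epoch) and a
no-detrend variant remain available as flags.

**PLV.** For channels x, y and saccades n, PLV = |(1/N) Σ_n exp(i(φ_n,y −
φ_n,x))| from the unit phasors of the windowed Fourier coefficients, per
frequency and time-within-interval; the mean phase difference is the
argument of the same sum. Peak-frequency readouts search f ≥ 15 Hz because
the deterministic MS-locked component dominates phases inside the DC
mainlobe of the 150-ms window (≈ 13 Hz half-width). Correlations of PLV
with electrode distance use all 4950 pairs; correlations with input
difference (the LFP-kernel-weighted mean drive under each electrode) use
pairs within 8 grid units (4 inter-I-cell spacings), since beyond that
sustained locking is absent. Significance uses permutation of pair labels
(1000 permutations); the transient window is 0–100 ms and the sustained
window 150–350 ms post-MS.

## Feedforward information transfer

**synSTA.** For each downstream neuron, triggers are its spikes inside the
period mask; for each *anatomically presynaptic* V1 neuron the spike count
in the lag window −8…−2 ms before the trigger is averaged over the 13
half-ms lag bins and over triggers. A shuffled estimate — equally many
uniformly drawn trigger times in the same mask, averaged over 10 draws —
is subtracted, so independent activity gives 0 in expectation. Per-neuron
profiles pool a neuron's downstream targets weighted by trigger count.

**Predictors.** Per V1 neuron and period: firing rate; synchrony (gamma
PLV of the neuron's nearest electrode with its four neighbouring
electrodes); PLV with the electrode over the shared downstream RF centre
(the synchrony field the downstream population reads out; used for the
receptive-field-shaping analysis); and phase — in the sustained period the
mean gamma phase of the downstream population potential relative to the
neuron's local electrode, θ = arg⟨exp(i(φ_V2 − φ_V1))⟩, so a downstream
population lagging its effective drivers has negative phase; in the
transient period, where less than two gamma cycles fit, first-spike
latency after MS onset. The gamma frequency is the sustained-window LFP
power peak within 25–40 Hz, measured per run.

**Mutual information.** Equal-width 8-bin histograms; I(X;Y) = H(X) +
H(Y) − H(XY) in bits, normalised by H(X) with X the synSTA. The
first-order small-sample bias (B−1)²/(2N ln 2) is reported alongside.

**Optimal phase.** Sustained-period records pooled over patches are binned
into 12 phase bins over (−π, π]; the reported optimum is the bin centre
maximising mean synSTA (bins holding < 1 % of samples are ignored).

## Arnold-tongue reconstruction

Detuning proxy: |Δ drive| under the two electrodes (input sets local gamma
frequency, measured at ≈ 23 → 37 Hz for uniform drive 2 → 6). Coupling
proxy: kernel-weighted reciprocal synaptic weight between the two
electrodes' excitatory neighbourhoods, normalised by kernel masses. Pairs
from several runs are pooled; PLV and mean phase at the run's gamma peak
± 4 Hz, window averaged, are binned on an 8 (equal-width detuning) × 6
(quantile coupling) grid; empty bins are missing, not zero. A map *has a
tongue* when the locked (PLV ≥ 0.5) detuning half-width grows with
coupling (Spearman ρ ≥ 0.5) *and* at least one weak-coupling row is fully
unlocked (the apex); a map is *uniformly locked* when every coupling row
keeps nonzero locked width — synchrony for any proxy combination, the
opposite of a tongue. The naive variance-flatness statistic does not
separate the two regimes here and is kept only as a descriptive output.

## Calibration

The per-projection N_S, g_S, the drive gain and the feedforward strengths
are not constrained by closed-form theory; they were fixed by a grid
search (`calibrate_gamma` automates the inner loop) requiring, in order:
a sustained-window LFP power and PLV peak inside 25–40 Hz; mean E rates of
5–15 Hz; sustained locking that decays with electrode distance (neighbour
pairs locked, maximal-distance pairs near the PLV floor); and a broadband
transient. The drive gain trades selectivity statistics against each
other: stronger drive deepens input-difference selectivity per run but
broadens sustained locking until the tongue's fixed PLV = 0.5 contour
saturates; the default (6) keeps the tongue dissociation and the per-seed
distance selectivity, with input-difference selectivity significant when
pairs are pooled across a few runs.

## Problem sizes

Analyses run at desk scale: 10–20 analysed MS intervals per run (one extra
integrated and discarded), 10 synthetic patches for the two-area
experiments, 5 seeds for robustness suites. A 20-interval run of the
2000-neuron network integrates 8.4 s of model time in roughly 15 s.

## Known limitations

* The MS-evoked onset reset is only partial under the specified noise
  (gamma-band inter-trial coherence ≈ 0.5–0.8 in the transient), so
  transient-window pair locking retains a measurable trace of the same
  distance/input structure that dominates the sustained window. The
  *contrast* between the periods reproduces; strict statistical
  *non-significance* of transient correlations does not (permutation tests
  over thousands of pairs detect correlations of |r| ≈ 0.1).
* The calibrated network operates in a sparse-PING regime (cells skip most
  gamma cycles). The shuffle-corrected synSTA then remains multiplicatively
  rate-dependent in both periods, so rate stays the strongest single
  predictor of sustained transfer in the pooled mutual-information
  decomposition, and the period contrast in input-vs-synchrony bias of the
  effective receptive fields is directional (≈ 7/10 patches) but weak.
  Full rate decoupling would need per-cycle volley participation (E rates
  near the gamma frequency), which conflicts with the physiological-rate
  bound and collapses the distance selectivity.
* No conduction delays, no synaptic plasticity, no slow (NMDA/GABA-B)
  synapses, no cortical layers, no feedback projections, no
  MS-direction-dependent spatial modulation; ocular drift enters only
  through the imposed-current noise.
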