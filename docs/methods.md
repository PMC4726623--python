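# Methods

## Model overview and assumptions

The package simulates vocal-motor learning as a closed loop: a spiking
reservoir drives muscles, muscles shape sound, sound is scored, and the
score gates plasticity. The loop embodies three assumptions: (i) motor
cortex can be approximated by a fixed recurrent spiking network whose
readout alone is plastic; (ii) the reward signal available to an infant
(their own interest, or caregiver responses) is well proxied by auditory
salience; (iii) credit assignment across the ~1-s sensory delay is
solved by synaptic eligibility traces gated by a global dopamine signal.

### Neurons and network

Izhikevich two-variable neurons, v' = 0.04v² + 5v + 140 − u + I,
u' = a(bv − u), spike at v ≥ 30 mV with reset v←c, u←u+d_reset.
Membrane potential is integrated with two 0.5-ms sub-steps per
millisecond (the standard stabilization for this model); the recovery
variable takes one full step. Excitatory and motor neurons are regular
spiking (a=0.02, b=0.2, c=−65, d_reset=8), inhibitory neurons fast
spiking (a=0.1, b=0.2, c=−65, d_reset=2). Parameters are homogeneous
within class; the mild per-neuron heterogeneity some variants of this
architecture use is omitted (the reservoir is fixed, so heterogeneity
only reshapes, not qualitatively changes, its dynamics).

Spike propagation delay is exactly 1 ms: a neuron crossing threshold
during the integration of ms t is registered, reset, and delivered as
synaptic current at ms t+1. There are no longer conduction delays.

Output→motor connectivity is all-to-all (200×200 by default). This is
the densest reading of the architecture and makes the weight matrix
directly comparable to its initial U(0,1) draw.

Neural state persists across trial boundaries: a run is one continuous
simulation (7,200,000 ms at full length), not 7200 independent seconds.
The 100-ms smoothing windows, however, are confined within each trial's
1000-ms raster (forced by the 900-sample output length).

### Plasticity

LTP-only, dopamine-gated STDP on the output→motor synapses with
periodic normalization in place of depression. Constants: dopamine
decay 0.995/ms, bump +1 per reward; presynaptic trace set to 0.1 on a
spike (set, not accumulated), decay 0.95/ms; eligibility decay 0.99 per
10-ms boundary; weight update every 10 ms, s ← min(s + e·d, 4), then
normalization, then eligibility decay. The per-ms statement order is
fixed and tested: dopamine decay → eligibility growth (from traces as
they stood *before* this ms's presynaptic spikes, so same-ms pre/post
pairs contribute nothing) → potentiation+cap → trace set-then-decay →
normalization+eligibility decay. The reward bump is applied at the
first millisecond of the trial after the evaluated vocalization,
implementing the distal-reward delay; within that millisecond, decay
runs before the bump.

Normalization divides by the **mean** synapse strength. The pseudocode
form of this rule is sometimes written with the grand sum as divisor;
dividing 40,000 synapses by their sum would collapse the weights four
orders of magnitude below their initial scale and destroy the motor
drive, so the mean (which keeps weights on the 0–4 scale the cap
implies) is used. A `normalize_by="sum"` switch exists for sensitivity
analysis. Because weights start positive and only grow before capping,
no weight can become negative; the suite asserts nonnegativity, the
post-cap bound, and |mean−1| < 1e-9 at every boundary of a 600-trial run.

### Motor interface

Per-pool spike counts are summed per millisecond *before* smoothing, so
the muscle drive scales with pool size — the property that makes the
motor-pool-size sweep meaningful (more neurons → larger amplitude).
Smoothed sample k (0-based) averages raster ms k..k+99; only fully
contained windows are used, giving 900 samples from a 1000-ms trial and
a lag of up to 99 ms. Net drive = m·(agonist − antagonist); m defaults
to 2 (the combination 200 motor neurons, m=2 is the reference default),
with the sweep grid covering m ∈ 2..8 and 50/100/200 motor neurons.

### Vocal tract surrogate

The reference pipeline renders sound with a full aerodynamic
articulatory synthesizer. Re-implementing that physics is out of scope;
the surrogate keeps exactly the two properties the learning loop
exploits:

1. **hard closure nonlinearity** — aperture(t) = clip(0.5 − muscle(t),
   0, 1); zero aperture silences the output;
2. **greater acoustic change near closure** — a two-pole resonance at
   F1(t) = 300 + 900·aperture(t) Hz (bandwidth 120 Hz) plus an
   amplitude factor aperture(t)^γ (γ=1), so equal aperture changes
   produce larger spectral/amplitude changes when the mouth is nearly
   closed.

The source is a 220-Hz pulse train (a generic adult-female fundamental;
the reference tool's f0 emerges from its physics and is not stated).
Its amplitude follows the lung-volume schedule (0 s, 0.1), (0.02 s,
0.1), (0.05 s, 0), (0.9 s, 0) linearly interpolated and normalized,
sustained by a slow exhalation recoil (τ = 0.5 s) so voicing persists
over the 0.9 s as it does in the aerodynamic model — the schedule
specifies volume, not amplitude, and this mapping is an explicit
inference. The rest aperture 0.5 places the mouth slightly open, the
configuration from which increases in mean muscle activation most
readily produce closure–opening alternation. Output gain is fixed at
0.5 with a safety renormalization only if the peak exceeds 1, so
relative sound levels between vocalizations are preserved.

`export_praat_script` writes the reference synthesizer's exact settings
(adult female speaker, 22050 Hz, the lungs schedule, Interarytenoid 0.5
and Hyoglossus 0.4 held throughout, per-ms Masseter and OrbicularisOris
targets equal to the muscle series) as a byte-stable script, so any
muscle series the model produces can be re-synthesized externally.

### Salience surrogate

Cochleagram: 20-ms Hann-windowed short-time spectra centered on each
millisecond, pooled into 32 log-spaced bands over 100–8000 Hz,
log-compressed with floor 1e-10. Transient trace: per band, the mean
log-energy over [t, t+20 ms) minus the mean over [t−20 ms, t), summed
across bands — onsets positive, offsets negative, steady state near
zero. Because the edge detector differences *log* energies, the score
is essentially invariant to global gain. The reference pipeline's final
stage — cortical filters trained on a speech corpus — is deliberately
not reproduced, so absolute scores live on this package's own scale;
every property the learning loop needs (S ≥ 0, polarity invariance,
monotone growth with the number of closure episodes) is scale-free and
tested.

One gain constant anchors the scale: `trace_scale = 2.25e-4`, chosen
once during surrogate construction so that vocalizations of untrained
default-configuration networks score a median of ~5 — i.e. they
straddle the reward threshold's fixed initial value of 4.5 the same way
the reference pipeline's starting vocalizations do (reported starting
salience ≈ 5.0 for the default parameter combination). The constant was
frozen before the learning experiments and is not a tuning knob.

### Reward threshold

θ starts at 4.5; r = 1 iff S > θ (strict); the indicator enters a
10-trial history; when the history holds ≥ 3 rewards θ grows by 0.1 and
the history is zeroed, so every increment requires three *new* rewards.
The history starts as ten zeros, so the criterion can fire within the
first 10 trials. θ is monotone non-decreasing and equals
4.5 + 0.1 × (criterion events). Yoked controls replay a reference run's
reward trial indices verbatim.

### Syllable-nucleus counting

Frame-wise RMS intensity (64-ms windows, 10-ms steps) in dB re the
waveform maximum, floored at −90 dB. Pauses ≥ 0.3 s below the −25 dB
silence threshold split the sound into utterance chunks; within each
chunk, peaks must exceed the silence threshold and be separated from
neighbours by dips ≥ 2 dB (prominence criterion), and are accepted only
if voiced at the peak — normalized autocorrelation ≥ 0.45 at a lag in
the 75–600 Hz pitch range, a threshold set so that steady pulse trains
pass and white noise fails. The reference tool's exact intensity
algorithm is not published; these choices preserve the semantics of its
three stated defaults, and thresholds are relative to the maximum, so
counts are gain-invariant. Whether the −25 dB is relative to the
maximum or to a high percentile is ambiguous; relative-to-maximum is
implemented and switchable.

## Synthetic data

The fixtures module generates every test input: Poisson spike rasters
with known rates, muscle series with closed-form mean/SD, harmonic
burst waveforms with known burst counts (10-ms raised-cosine ramps,
≥ 0.35-s gaps so each burst satisfies every nucleus criterion), their
unvoiced white-noise twins, and salience sequences paired with a
literal transcription of the threshold procedure. These emulate the
*structure* real model output has (voiced bursts, closure episodes,
reward streaks) but not real infant audio: passing tests demonstrate
the algorithms implement their definitions and that the learning loop's
directional claims hold under the surrogates, not that absolute
salience or syllable counts match recordings of infants or the
reference synthesizers.

## Problem sizes and numerical choices

Full-length runs are 7200 trials. The packaged learning experiment uses
5 seeds × 1200 trials per arm (reinforced + yoked), a scale at which
the directional effects (salience increase for reinforced but not yoked
runs; agonist/antagonist weight ratio above the yoked ratio; upward
muscle mean/SD trends; positive standardized regression coefficients of
salience on muscle SD and mean; more syllable nuclei in the final than
the first minute) are already resolvable; the invariant suite uses one
600-trial run. Effect sizes grow with run length, so these scaled runs
are conservative with respect to the full-length behaviour.

The per-ms loop exists twice: a pure-numpy reference API (unit-testable
operation by operation) and a fused numba kernel used by the
orchestrator, pinned to the reference by an exact equivalence test over
300 ms. Simulations are bit-reproducible given (seed, config): one
master seed spawns named substreams for topology, initial weights and
noise, so the topology does not depend on run length. Trend summaries
use binned means with bootstrap CIs instead of the GAM-with-random-
effects fits a full statistical analysis would use — the claims tested
here are directional, not fit-specific — and the regression z-scores
predictors and response, so coefficients are standardized betas
comparable in sign (not value) to reference analyses.

## Known limitations

Absolute salience values, syllable counts and weight-ratio magnitudes
are not comparable to pipelines built on the full articulatory
synthesizer and trained salience model; only signs, orderings and
invariants are. One motor degree of freedom; no tongue, velum, larynx
or lung control; no perceptual system; binary rewards; adult-female
tract geometry stands in for the infant tract.
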