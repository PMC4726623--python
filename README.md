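# babblesim

A computational-neuroscience simulation of how canonical babbling — the
consonant–vowel alternating vocalizations human infants begin producing
around 7 months — can be acquired by a spiking neural network through
reward-modulated plasticity.

## The model

A reservoir of 1000 recurrently connected Izhikevich neurons (80%
regular-spiking excitatory, 20% fast-spiking inhibitory, each with 100
random outgoing synapses; inhibitory neurons target only excitatory
ones) produces spontaneous oscillatory activity driven solely by
per-millisecond input currents drawn uniformly from ±6.5 pA. 200 of the
excitatory neurons are *output* neurons projecting through plastic
synapses to a motor population split into agonist and antagonist pools
(100 + 100). Every second, the pooled spike counts of each motor pool
are smoothed with a 100-ms moving average; the antagonist series is
subtracted from the agonist series and scaled by a muscle constant *m*,
yielding a 900-ms net activation of the jaw-closing (masseter) and
lip-closing (orbicularis oris) muscles of a one-degree-of-freedom vocal
tract. When activation exceeds the slightly-open rest aperture, the
mouth closes and airflow stops — a consonantal closure.

Each 0.9-s vocalization is scored for auditory salience

    S(v) = Σ_{t=151..900 ms} |s(v, t)|

where s(v, t) is a per-ms trace of spectrotemporal onset/offset
transients in a cochleagram (the first 150 ms are excluded as pure
stimulus-onset response). If S(v) exceeds an adaptive threshold θ —
initialized at 4.5, raised by 0.1 whenever at least 3 of the last 10
trials were rewarded — the network receives a reward: global dopamine
d increases by 1. Dopamine (decay 0.995/ms) gates LTP-only STDP on the
output→motor synapses via eligibility traces: each output-neuron spike
sets a presynaptic trace to 0.1 (decay 0.95/ms); each motor-neuron spike
adds the traces onto the eligibility of its incoming synapses; every
10 ms the weights grow by eligibility × dopamine (cap 4), are normalized
to unit mean, and eligibility decays by 0.99. Because consonant–vowel
alternation is what makes a sound salient, the loop selectively
reinforces the motor patterns that produce syllabic sounds. *Yoked
controls* — runs that replay another run's reward times, decoupled from
their own behaviour — isolate reward contingency as the cause.

The heavy articulatory physics and the trained cortical-filter stage of
the original salience pipeline are replaced by documented surrogates
(see `docs/methods.md`); `babblesim.vocal_tract.export_praat_script`
emits bit-stable scripts carrying the exact reference synthesizer
settings (adult female tract, 22050 Hz, lung-volume schedule, fixed
Interarytenoid 0.5 / Hyoglossus 0.4) for re-synthesis with the real tool.

## Worked example

A scaled run (1200 trials ≈ 20 simulated minutes) against its yoked
control:

```python
from babblesim import RunConfig, run_simulation, analysis

ref = run_simulation(RunConfig(seed=101, n_trials=1200))
yok = run_simulation(RunConfig(seed=1101, n_trials=1200,
                               yoked_reward_trials=tuple(ref.reward_trials)))
for name, res in [("reinforced", ref), ("yoked", yok)]:
    s0, s1 = analysis.start_end_summary(res.log)
    ratio, wsd = analysis.weight_summary(res.s_final, res.topology)
    print(f"{name}: salience {s0:.2f} -> {s1:.2f}, "
          f"agonist/antagonist weight ratio {ratio:.3f}")
```

prints

```
reinforced: salience 4.92 -> 5.24, agonist/antagonist weight ratio 1.079
yoked: salience 5.12 -> 5.19, agonist/antagonist weight ratio 1.047
```

The reinforced run raises the salience of its vocalizations between the
first and last simulated minute while the yoked control does not, and
its plastic weights develop a bias toward the agonist (mouth-closing)
motor pool — the mechanism by which the network learns to alternate
between closure and opening. Full-length runs use
`RunConfig(n_trials=7200)` (2 simulated hours). A CLI wraps the same
machinery: `babblesim run --seed 0 --trials 7200 --out rundir`,
`babblesim score sound.wav`, `babblesim nuclei sound.wav`,
`babblesim analyze rundir`, `babblesim sweep --grid grid.yaml --out summary.csv`.

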