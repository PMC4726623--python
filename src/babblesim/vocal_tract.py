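"""One-degree-of-freedom articulatory surrogate and Praat script export.

The reference pipeline drives the masseter and orbicularis oris of a full
aerodynamic articulatory synthesizer (adult female tract, 22050 Hz,
lung-volume schedule (0 s, 0.1), (0.02 s, 0.1), (0.05 s, 0),
(0.9 s, 0), Interarytenoid 0.5 and Hyoglossus 0.4 held throughout).
Re-implementing that physics is out of scope here; this module provides

* a *surrogate* synthesizer that preserves the two properties the
  learning dynamics depend on: a hard airflow cutoff once the muscle
  activation closes the mouth, and larger acoustic change per unit
  aperture change near closure (through a moving first-formant resonance
  and an aperture-dependent amplitude); and
* :func:`export_praat_script`, which writes a byte-stable script that
  reproduces the exact reference synthesizer settings for any muscle
  series, so any vocalization can be re-synthesized with the real tool.

The surrogate maps net muscle activation to lip/jaw aperture as
``aperture(t) = clip(rest_aperture - muscle(t), 0, 1)``, excites a pulse
train at a fixed fundamental whose amplitude follows a lungs-driven
exhalation envelope, filters it with a two-pole resonance at
``F1(t) = F1_closed + (F1_open - F1_closed) * aperture(t)`` and finally
scales the result by ``aperture(t) ** gamma``; zero aperture is silence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "SynthConfig",
    "Waveform",
    "aperture_trajectory",
    "lungs_envelope",
    "synthesize_surrogate",
    "export_praat_script",
    "write_wav",
    "read_wav",
]

DEFAULT_LUNGS_SCHEDULE = ((0.0, 0.1), (0.02, 0.1), (0.05, 0.0), (0.9, 0.0))


@dataclass(frozen=True)
class SynthConfig:
    sample_rate: int = 22050
    duration_s: float = 0.9
    f0: float = 220.0                      # voicing fundamental, Hz
    rest_aperture: float = 0.5             # slightly-open rest position, (0, 1]
    closure_threshold: float = 0.0         # aperture at/below which airflow stops
    lungs_schedule: tuple = DEFAULT_LUNGS_SCHEDULE   # (time s, target lung volume)
    interarytenoid: float = 0.5
    hyoglossus: float = 0.4
    envelope_exponent: float = 1.0         # gamma in aperture**gamma
    f1_closed: float = 300.0               # first-formant map, Hz
    f1_open: float = 1200.0
    resonance_bw: float = 120.0            # resonance bandwidth, Hz
    exhalation_tau_s: float = 0.5          # slow lung-recoil decay of voicing
    output_gain: float = 0.5

    def __post_init__(self) -> None:
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if not 0.0 < self.rest_aperture <= 1.0:
            raise ValueError("rest_aperture must lie in (0, 1]")

    @property
    def n_samples(self) -> int:
        return round(self.duration_s * self.sample_rate)


@dataclass(frozen=True)
class Waveform:
    samples: np.ndarray     # mono, float in [-1, 1]
    sample_rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if not np.isfinite(samples).all():
            raise ValueError("waveform contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate


def aperture_trajectory(muscle, config: SynthConfig = SynthConfig()) -> np.ndarray:
    """Per-ms lip/jaw aperture: clip(rest_aperture - muscle, 0, 1)."""
    values = muscle.values if hasattr(muscle, "values") else np.asarray(muscle, float)
    return np.clip(config.rest_aperture - values, 0.0, 1.0)


def lungs_envelope(config: SynthConfig, n_ms: int) -> np.ndarray:
    """Source-amplitude envelope derived from the lung-volume schedule.

    The schedule specifies target lung *volume*; the surrogate maps it to a
    voicing amplitude by normalizing to the schedule maximum and letting a
    slow exponential recoil (time constant ``exhalation_tau_s``) sustain
    voicing after the scheduled volume has dropped, so phonation persists
    over the full vocalization as it does in the aerodynamic synthesizer.
    """
    t = (np.arange(n_ms) + 0.5) * 1e-3
    times = np.array([p[0] for p in config.lungs_schedule])
    targets = np.array([p[1] for p in config.lungs_schedule])
    vmax = targets.max()
    if vmax <= 0:
        return np.zeros(n_ms)
    scheduled = np.interp(t, times, targets) / vmax
    # recoil starts where the scheduled volume last leaves its maximum
    t_release = times[np.flatnonzero(targets == vmax)[-1]]
    recoil = np.exp(-np.maximum(t - t_release, 0.0) / config.exhalation_tau_s)
    return np.maximum(scheduled, recoil)


@njit(cache=True)
def _resonator_kernel(source, f1_per_ms, gain_per_ms, block_edges, sample_rate, bw):
    """Per-sample two-pole resonance with per-ms coefficient updates."""
    out = np.zeros_like(source)
    y1 = 0.0
    y2 = 0.0
    for k in range(len(block_edges) - 1):
        theta = 2.0 * np.pi * f1_per_ms[k] / sample_rate
        r = np.exp(-np.pi * bw / sample_rate)
        b0 = (1.0 - r * r) * np.sin(theta)
        a1 = 2.0 * r * np.cos(theta)
        a2 = -r * r
        g = gain_per_ms[k]
        for n in range(block_edges[k], block_edges[k + 1]):
            y = b0 * source[n] + a1 * y1 + a2 * y2
            y2 = y1
            y1 = y
            out[n] = g * y
    return out


def synthesize_surrogate(muscle, config: SynthConfig = SynthConfig()) -> Waveform:
    """Render a muscle series into a 0.9-s waveform (surrogate vocal tract).

    Deterministic: identical inputs give bit-identical output.
    """
    aperture = aperture_trajectory(muscle, config)
    n_ms = len(aperture)
    n_samples = config.n_samples
    fs = config.sample_rate

    # glottal source: pulse train at f0, amplitude from the lungs envelope
    env = lungs_envelope(config, n_ms)
    source = np.zeros(n_samples)
    period = fs / config.f0
    pulse_idx = np.round(np.arange(0, n_samples, period)).astype(np.int64)
    pulse_idx = pulse_idx[pulse_idx < n_samples]
    env_at = env[np.minimum((pulse_idx / fs * 1e3).astype(np.int64), n_ms - 1)]
    source[pulse_idx] = env_at

    open_frac = np.where(aperture > config.closure_threshold, aperture, 0.0)
    f1 = config.f1_closed + (config.f1_open - config.f1_closed) * aperture
    gain = open_frac ** config.envelope_exponent

    block_edges = np.round(np.arange(n_ms + 1) * (n_samples / n_ms)).astype(np.int64)
    filtered = _resonator_kernel(source, f1, gain, block_edges, float(fs),
                                 config.resonance_bw)

    samples = config.output_gain * filtered
    peak = np.abs(samples).max()
    if peak > 1.0:
        samples = samples / peak
    return Waveform(samples=samples, sample_rate=fs)


def export_praat_script(muscle, config: SynthConfig = SynthConfig(), path=None) -> str:
    """Script for the external articulatory synthesizer, bit-exact per input.

    Speaker is the adult female model; the lung-volume schedule, the
    Interarytenoid (0.5) and Hyoglossus (0.4) settings are written
    verbatim, and the masseter and orbicularis oris both receive one
    target per millisecond equal to the muscle series.
    """
    values = muscle.values if hasattr(muscle, "values") else np.asarray(muscle, float)
    dur = config.duration_s
    lines = [
        'speaker = Create Speaker: "speaker", "Female", "2"',
        f'artword = Create Artword: "vocalization", {dur:.6f}',
        "selectObject: artword",
    ]
    for t, target in config.lungs_schedule:
        lines.append(f'Set target: {t:.6f}, {target:.6f}, "Lungs"')
    for t in (0.0, dur):
        lines.append(f'Set target: {t:.6f}, {config.interarytenoid:.6f}, "Interarytenoid"')
    for t in (0.0, dur):
        lines.append(f'Set target: {t:.6f}, {config.hyoglossus:.6f}, "Hyoglossus"')
    for muscle_name in ("Masseter", "OrbicularisOris"):
        for k, value in enumerate(values):
            lines.append(f'Set target: {k * 1e-3:.6f}, {value:.6f}, "{muscle_name}"')
    lines += [
        "selectObject: speaker, artword",
        f"To Sound: {config.sample_rate}, 25, 0, 0, 0, 0, 0, 0, 0, 0, 0",
    ]
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def write_wav(path, waveform: Waveform) -> None:
    """Write 16-bit PCM mono WAV."""
    from scipy.io import wavfile

    clipped = np.clip(waveform.samples, -1.0, 1.0)
    wavfile.write(path, waveform.sample_rate, (clipped * 32767.0).astype(np.int16))


def read_wav(path) -> Waveform:
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim > 1:
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return Waveform(samples=np.asarray(data, dtype=float), sample_rate=int(rate))
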