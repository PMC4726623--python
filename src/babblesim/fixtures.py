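"""Synthetic test inputs with known ground truth.

Every generator is seed-deterministic and returns its expected ground
truth alongside the data, so tests never recompute expectations with the
code under test: burst waveforms carry their burst count, reward
sequences carry an independently transcribed threshold trajectory, and
muscle series carry closed-form means and standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motor_interface import MuscleSeries
from .vocal_tract import Waveform

__all__ = [
    "make_burst_waveform",
    "make_noise_burst_waveform",
    "make_reward_sequence",
    "make_muscle_series",
    "make_spike_raster",
]


def _burst_envelope(n_bursts: int, burst_dur_s: float, gap_s: float,
                    fs: int, duration_s: float | None) -> tuple[np.ndarray, int]:
    needed = n_bursts * burst_dur_s + (n_bursts + 1) * gap_s
    if duration_s is None:
        duration_s = max(0.9, needed)
    if needed > duration_s + 1e-9:
        raise ValueError(
            f"{n_bursts} bursts of {burst_dur_s}s with {gap_s}s gaps do not fit "
            f"in {duration_s}s")
    n = round(duration_s * fs)
    env = np.zeros(n)
    ramp_len = int(0.010 * fs)  # 10-ms raised-cosine ramps
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_len) / ramp_len))
    for k in range(n_bursts):
        start = int(round((gap_s + k * (burst_dur_s + gap_s)) * fs))
        stop = min(start + int(round(burst_dur_s * fs)), n)
        if stop - start <= 2 * ramp_len:
            raise ValueError("burst too short for the 10-ms ramps")
        env[start:stop] = 1.0
        env[start:start + ramp_len] = ramp
        env[stop - ramp_len:stop] = ramp[::-1]
    return env, n


def make_burst_waveform(k: int, f0: float = 220.0, burst_dur_s: float = 0.15,
                        gap_s: float = 0.35, fs: int = 22050,
                        duration_s: float | None = None,
                        n_harmonics: int = 5) -> tuple[Waveform, int]:
    """k voiced (harmonic) bursts separated by silences >= gap_s.

    Returns the waveform and the ground-truth nucleus count k.  With the
    default geometry every burst satisfies all detector criteria: well
    above the silence floor, voiced (periodic at f0), and separated by
    pauses longer than the minimum pause duration.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    env, n = _burst_envelope(k, burst_dur_s, gap_s, fs, duration_s)
    t = np.arange(n) / fs
    tone = sum(np.sin(2.0 * np.pi * f0 * h * t) / h for h in range(1, n_harmonics + 1))
    tone = tone / np.abs(tone).max() if k > 0 else tone
    return Waveform(samples=0.8 * env * tone, sample_rate=fs), k


def make_noise_burst_waveform(k: int, seed: int = 0, burst_dur_s: float = 0.15,
                              gap_s: float = 0.35, fs: int = 22050,
                              duration_s: float | None = None) -> tuple[Waveform, int]:
    """Unvoiced control: the same burst envelope filled with white noise.

    Ground truth for the nucleus detector is 0 (voicing rejection).
    """
    env, n = _burst_envelope(k, burst_dur_s, gap_s, fs, duration_s)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    noise /= max(np.abs(noise).max(), 1e-12)
    return Waveform(samples=0.8 * env * noise, sample_rate=fs), 0


def make_reward_sequence(pattern) -> dict:
    """Salience sequence plus an independent threshold-trajectory oracle.

    The oracle below is a literal, line-by-line transcription of the
    adaptive-threshold procedure, kept free of any package state
    machinery so it can arbitrate the reward module.
    """
    saliences = [float(S) for S in pattern]
    theta = 4.5
    h = [0] * 10
    r_list, theta_list = [], []
    for S in saliences:
        if S > theta:
            r = 1
        else:
            r = 0
        theta_list.append(theta)   # threshold in force at evaluation
        h = h[1:] + [r]
        if sum(h) >= 3:
            theta = theta + 0.1
            h = [0] * 10
        r_list.append(r)
    return {"S": saliences, "r": r_list, "theta_at_eval": theta_list,
            "theta_final": theta}


def make_muscle_series(shape: str, amplitude: float = 1.0, offset: float = 0.0,
                       n_ms: int = 900, period_ms: int = 100,
                       trial_index: int = 0) -> tuple[MuscleSeries, float, float]:
    """Muscle series with closed-form mean and population SD.

    shapes: ``constant`` (mean=offset, sd=0), ``sine`` over whole periods
    (mean=offset, sd=amplitude/sqrt(2)), ``step`` half offset / half
    offset+amplitude (mean=offset+amplitude/2, sd=amplitude/2).
    """
    t = np.arange(n_ms)
    if shape == "constant":
        values = np.full(n_ms, offset)
        mean, sd = offset, 0.0
    elif shape == "sine":
        if n_ms % period_ms != 0:
            raise ValueError("sine fixture requires whole periods")
        values = offset + amplitude * np.sin(2.0 * np.pi * t / period_ms)
        mean, sd = offset, amplitude / np.sqrt(2.0)
    elif shape == "step":
        values = np.full(n_ms, offset)
        values[n_ms // 2:] = offset + amplitude
        mean, sd = offset + amplitude / 2.0, amplitude / 2.0
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return MuscleSeries(values=values, trial_index=trial_index), float(mean), float(sd)


def make_spike_raster(n_ms: int, rate_per_ms: float, seed: int = 0) -> tuple[np.ndarray, float]:
    """Poisson pooled spike-count raster; ground truth is the expected rate."""
    rng = np.random.default_rng(seed)
    return rng.poisson(rate_per_ms, size=n_ms).astype(float), float(rate_per_ms)
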