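"""Syllable-nucleus counting from intensity peaks plus a voicing check.

A syllable nucleus is the loudest, typically vocalic, part of a
syllable.  The detector follows the standard intensity-peak approach:
frame-wise intensity in dB relative to the waveform's maximum; candidate
peaks must rise above a silence threshold (-25 dB re max), be separated
from neighbouring candidates by intensity dips of at least 2 dB, and be
voiced at the peak (an autocorrelation pitch found between 75 and
600 Hz).  Pauses of at least 0.3 s split the sound into independently
analysed utterance chunks.  All thresholds are relative, so the count is
invariant to global gain changes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = ["NucleiParams", "intensity_contour", "is_voiced_frame", "count_nuclei"]

INTENSITY_FLOOR_DB = -90.0


@dataclass(frozen=True)
class NucleiParams:
    silence_threshold_db: float = -25.0   # re maximum intensity
    min_dip_db: float = 2.0
    min_pause_s: float = 0.3
    pitch_floor_hz: float = 75.0
    pitch_ceiling_hz: float = 600.0
    frame_step_s: float = 0.01
    frame_window_s: float = 0.064
    voicing_threshold: float = 0.45       # normalized autocorrelation peak

    def __post_init__(self) -> None:
        if not self.min_dip_db > 0:
            raise ValueError("min_dip_db must be positive")
        if not self.pitch_floor_hz < self.pitch_ceiling_hz:
            raise ValueError("pitch floor must lie below the ceiling")


def _frames(samples: np.ndarray, fs: int, params: NucleiParams):
    step = max(1, int(round(params.frame_step_s * fs)))
    width = max(2, int(round(params.frame_window_s * fs)))
    if len(samples) < width:
        raise ValueError("waveform shorter than one analysis frame")
    starts = np.arange(0, len(samples) - width + 1, step)
    centers = starts + width // 2
    return starts, centers, width, step


def intensity_contour(waveform, params: NucleiParams = NucleiParams()) -> np.ndarray:
    """Frame-wise RMS intensity in dB re the waveform maximum, floored at -90 dB."""
    samples = waveform.samples if hasattr(waveform, "samples") else np.asarray(waveform, float)
    fs = waveform.sample_rate if hasattr(waveform, "sample_rate") else 22050
    starts, _, width, _ = _frames(samples, fs, params)
    idx = starts[:, None] + np.arange(width)[None, :]
    rms = np.sqrt((samples[idx] ** 2).mean(axis=1))
    ref = rms.max()
    if ref <= 0:
        return np.full(len(starts), INTENSITY_FLOOR_DB)
    db = 20.0 * np.log10(np.maximum(rms / ref, 10 ** (INTENSITY_FLOOR_DB / 20.0)))
    return db


def is_voiced_frame(samples: np.ndarray, fs: int, center: int,
                    params: NucleiParams = NucleiParams()) -> bool:
    """Autocorrelation voicing check on a window around ``center``.

    Voiced iff the normalized autocorrelation has a peak of at least the
    voicing threshold at a lag corresponding to a pitch in
    [pitch_floor, pitch_ceiling].
    """
    # window long enough for two periods of the pitch floor
    width = int(round(2.5 * fs / params.pitch_floor_hz))
    lo = max(0, center - width // 2)
    hi = min(len(samples), lo + width)
    seg = samples[lo:hi] - samples[lo:hi].mean()
    if len(seg) < 4 or not seg.any():
        return False
    ac = np.correlate(seg, seg, mode="full")[len(seg) - 1:]
    if ac[0] <= 0:
        return False
    ac = ac / ac[0]
    lag_min = int(np.floor(fs / params.pitch_ceiling_hz))
    lag_max = int(np.ceil(fs / params.pitch_floor_hz))
    lag_max = min(lag_max, len(ac) - 1)
    if lag_min >= lag_max:
        return False
    return bool(ac[lag_min:lag_max + 1].max() >= params.voicing_threshold)


def count_nuclei(waveform, params: NucleiParams = NucleiParams()) -> int:
    """Number of voiced intensity peaks satisfying the nucleus criteria."""
    samples = waveform.samples if hasattr(waveform, "samples") else np.asarray(waveform, float)
    fs = waveform.sample_rate if hasattr(waveform, "sample_rate") else 22050
    if not np.asarray(samples).any():
        return 0
    db = intensity_contour(waveform, params)
    _, centers, _, step = _frames(np.asarray(samples, float), fs, params)
    threshold = params.silence_threshold_db  # re max = 0 dB

    # split into utterance chunks at pauses >= min_pause_s
    silent = db < threshold
    min_pause_frames = max(1, int(round(params.min_pause_s / params.frame_step_s)))
    chunks = []
    start = None
    run_silent = 0
    for i, s in enumerate(silent):
        if not s:
            if start is None:
                start = i
            run_silent = 0
        else:
            run_silent += 1
            if start is not None and run_silent >= min_pause_frames:
                chunks.append((start, i - run_silent + 1))
                start = None
    if start is not None:
        chunks.append((start, len(db)))

    count = 0
    for lo, hi in chunks:
        seg = db[lo:hi]
        if len(seg) == 0:
            continue
        # candidate peaks above the silence threshold, separated by dips
        # of at least min_dip_db on both sides (prominence criterion)
        peaks, _ = find_peaks(np.concatenate([[INTENSITY_FLOOR_DB], seg,
                                              [INTENSITY_FLOOR_DB]]),
                              height=threshold, prominence=params.min_dip_db)
        for p in peaks - 1:
            if is_voiced_frame(np.asarray(samples, float), fs, centers[lo + p], params):
                count += 1
    return count
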