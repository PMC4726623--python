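"""From motor-pool spike rasters to the net muscle-activation series.

Spikes are summed across each pool per millisecond, smoothed with a
100-ms moving average over the trial's 1000 ms (yielding a 900-sample
series; only fully contained windows are used), and the smoothed
antagonist activity is subtracted from the smoothed agonist activity.
The difference, scaled by the muscle constant ``m``, jointly drives the
masseter and orbicularis oris: positive values close the jaw and lips,
negative values open them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MotorConfig", "MuscleSeries", "smooth_spikes", "net_muscle"]


@dataclass(frozen=True)
class MotorConfig:
    window_ms: int = 100
    trial_ms: int = 1000
    m: float = 2.0    # muscle scaling constant; the sweep covers 2..8

    def __post_init__(self) -> None:
        if not self.window_ms < self.trial_ms:
            raise ValueError("smoothing window must be shorter than the trial")
        if not self.m > 0:
            raise ValueError(f"muscle scaling m must be positive, got {self.m}")

    @property
    def series_len(self) -> int:
        return self.trial_ms - self.window_ms


@dataclass(frozen=True)
class MuscleSeries:
    """900-sample per-ms net muscle activation for one vocalization."""

    values: np.ndarray
    trial_index: int = 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("muscle series contains non-finite values")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def smooth_spikes(raster: np.ndarray, window_ms: int = 100) -> np.ndarray:
    """Moving average of a pooled per-ms spike-count raster.

    Output element ``k`` is the mean of raster elements ``k .. k+window-1``
    (0-based); a 1000-ms raster with a 100-ms window gives 900 samples.
    """
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 1 or len(raster) < window_ms:
        raise ValueError("raster must be 1-D and at least one window long")
    kernel = np.full(window_ms, 1.0 / window_ms)
    return np.convolve(raster, kernel, mode="valid")[: len(raster) - window_ms]


def net_muscle(agonist_smoothed: np.ndarray, antagonist_smoothed: np.ndarray,
               m: float, trial_index: int = 0) -> MuscleSeries:
    """m * (agonist - antagonist), elementwise.

    Negative values mean antagonist dominance, i.e. mouth opening.
    """
    agonist_smoothed = np.asarray(agonist_smoothed, dtype=float)
    antagonist_smoothed = np.asarray(antagonist_smoothed, dtype=float)
    if agonist_smoothed.shape != antagonist_smoothed.shape:
        raise ValueError("agonist and antagonist series must have equal length")
    if not m > 0:
        raise ValueError("muscle scaling m must be positive")
    return MuscleSeries(values=m * (agonist_smoothed - antagonist_smoothed),
                        trial_index=trial_index)
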