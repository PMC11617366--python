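"""Infrared skin-temperature smoothing and skin-vs-rectal error analysis.

Raw collar infrared thermography (IRT) readings of the neck are noisy and
carry short artifact spikes (head shakes, momentary loss of skin contact).
A short rolling *median* — 1 s by default, scaled to the sensor frame
rate — removes isolated spikes without smearing the underlying trend.
The smoothed trace is summarised with empirical quantiles and compared
against a per-animal rectal baseline, the conventional core-temperature
reference in livestock monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import _check_uniform


@dataclass
class TemperatureTrace:
    """Raw skin-temperature series with its rectal reference baseline (°C)."""

    t_s: np.ndarray
    temp_c: np.ndarray
    rectal_baseline_c: float | None = None
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.temp_c = np.asarray(self.temp_c, dtype=float)
        if self.t_s.size == 0:
            raise ValueError("empty temperature trace")
        if self.t_s.size != self.temp_c.size:
            raise ValueError("t_s and temp_c lengths differ")
        if self.t_s.size >= 2:
            self.sample_rate_hz = 1.0 / _check_uniform(self.t_s)
        else:
            self.sample_rate_hz = float("nan")


@dataclass
class SmoothedTrace:
    """Median-filtered temperature series; keeps the source baseline."""

    t_s: np.ndarray
    temp_c: np.ndarray
    window_s: float
    rectal_baseline_c: float | None = None
    animal_id: str = ""


@dataclass
class TempSummary:
    quantiles: dict[float, float]
    median_c: float


@dataclass
class TempErrorStats:
    """Per-animal rectal-minus-skin error distribution."""

    animal_id: str
    median_error_c: float
    iqr_c: float
    error_samples_c: np.ndarray = field(repr=False)


def rolling_median(trace: TemperatureTrace, window_s: float = 1.0) -> SmoothedTrace:
    """Centered rolling-median filter over ``window_s`` seconds.

    The window is ``round(window_s × rate)`` samples, forced odd so the
    filter is symmetric; at the edges the window shrinks (no padding, no
    fabricated values).  Output length equals input length.
    """
    if window_s <= 0:
        raise ValueError("window_s must be positive")
    rate = trace.sample_rate_hz
    if not np.isfinite(rate):
        raise ValueError("trace too short to infer sample rate")
    w = int(round(window_s * rate))
    w = max(1, w)
    if w % 2 == 0:
        w += 1
    smoothed = (
        pd.Series(trace.temp_c)
        .rolling(window=w, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    return SmoothedTrace(
        t_s=trace.t_s.copy(),
        temp_c=smoothed,
        window_s=window_s,
        rectal_baseline_c=trace.rectal_baseline_c,
        animal_id=trace.animal_id,
    )


def summarize(
    smoothed: SmoothedTrace | TemperatureTrace,
    probs: Sequence[float] = (0.75, 0.90, 0.95, 0.97),
) -> TempSummary:
    """Empirical quantiles (linear interpolation of order statistics) + median."""
    values = np.asarray(smoothed.temp_c, dtype=float)
    if values.size == 0:
        raise ValueError("empty trace")
    probs = tuple(float(p) for p in probs)
    if any(not 0.0 < p < 1.0 for p in probs):
        raise ValueError("quantile probabilities must lie in (0, 1)")
    qs = np.quantile(values, probs, method="linear")
    return TempSummary(
        quantiles={p: float(q) for p, q in zip(probs, qs)},
        median_c=float(np.median(values)),
    )


def skin_rectal_error(smoothed: SmoothedTrace) -> TempErrorStats:
    """Rectal-baseline minus smoothed-skin error distribution.

    Positive medians mean the skin reads below the rectal reference, the
    expected direction for surface measurements.
    """
    if smoothed.rectal_baseline_c is None:
        raise ValueError("trace has no rectal baseline")
    errors = smoothed.rectal_baseline_c - np.asarray(smoothed.temp_c, dtype=float)
    q1, q3 = np.quantile(errors, [0.25, 0.75])
    return TempErrorStats(
        animal_id=smoothed.animal_id,
        median_error_c=float(np.median(errors)),
        iqr_c=float(q3 - q1),
        error_samples_c=errors,
    )
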