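"""Sliding-window segmentation of 9-channel IMU streams and per-channel
time-series features.

Each window is summarised, channel by channel, with seven statistics:
mean (F1), population variance (F2), root mean square (F3), skewness (F4),
excess kurtosis (F5), energy Σx² (F6) and integral of absolute value
Σ|x|·dt (F8).  A 9-channel window therefore yields a 63-long feature
vector, flattened channel-major.  Moment conventions are population (1/n);
degenerate windows (zero variance) map skewness and kurtosis to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .labels import BehaviorLabel

#: Canonical channel order: accelerometer (g), gyroscope (dps), magnetometer.
CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz", "mx", "my", "mz")

#: CSV column names (with units) matching CHANNELS order.
CHANNEL_COLUMNS: tuple[str, ...] = (
    "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps", "mx", "my", "mz",
)

FEATURE_IDS: tuple[str, ...] = ("F1", "F2", "F3", "F4", "F5", "F6", "F8")

#: Flattened feature names, channel-major: ax_F1 … ax_F8, ay_F1, …
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{ch}_{fid}" for ch in CHANNELS for fid in FEATURE_IDS
)

_REL_TOL = 1e-6  # uniform-sampling tolerance, relative to the sample period


def _check_uniform(t_s: np.ndarray) -> float:
    """Validate uniform, increasing timestamps; return the sample period."""
    if t_s.ndim != 1 or t_s.size < 2:
        raise ValueError("need at least two timestamps")
    dt = np.diff(t_s)
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing")
    period = float(np.median(dt))
    if np.max(np.abs(dt - period)) > _REL_TOL * period:
        raise ValueError("non-uniform sampling beyond tolerance")
    return period


@dataclass
class SensorStream:
    """Uniformly sampled 9-channel IMU record.

    ``data`` is a (9, n) array in :data:`CHANNELS` order: accelerometer in g,
    gyroscope in degrees per second, magnetometer in arbitrary units.
    """

    t_s: np.ndarray
    data: np.ndarray
    sample_rate_hz: float
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(CHANNELS), self.t_s.size):
            raise ValueError(
                f"data must be shaped (9, {self.t_s.size}), got {self.data.shape}"
            )
        period = _check_uniform(self.t_s)
        if abs(period * self.sample_rate_hz - 1.0) > 1e-6:
            raise ValueError("sample_rate_hz inconsistent with timestamps")

    @property
    def n_samples(self) -> int:
        return self.t_s.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        return self.data[CHANNELS.index(name)]


@dataclass
class WindowSpec:
    """How to tile a stream into analysis windows.

    A window receives the label covering a *strict majority* of its duration
    (coverage > ``min_label_coverage``); windows without one stay unlabeled
    and are excluded from training.
    """

    length_s: float = 10.0
    overlap_fraction: float = 0.0
    min_label_coverage: float = 0.5

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0.5 <= self.min_label_coverage <= 1.0:
            raise ValueError("min_label_coverage must be in [0.5, 1]")

    def n_samples(self, rate_hz: float) -> int:
        n = int(round(self.length_s * rate_hz))
        if n < 2:
            raise ValueError("window must span at least 2 samples")
        return n


@dataclass
class LabeledWindow:
    """One fixed-length window of 9-channel samples with an optional label."""

    start_s: float
    samples: np.ndarray  # (9, n)
    label: Optional[BehaviorLabel]
    animal_id: str = ""


@dataclass
class FeatureVector:
    """63 per-channel features, flattened channel-major."""

    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES


@dataclass
class FeatureMatrix:
    """Rows of feature vectors aligned with labels, animal ids and start times."""

    X: np.ndarray  # (m, 63)
    labels: list
    animal_ids: list
    start_s: np.ndarray
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        m = self.X.shape[0]
        if not (len(self.labels) == len(self.animal_ids) == self.start_s.size == m):
            raise ValueError("misaligned FeatureMatrix fields")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def y(self) -> np.ndarray:
        return np.array([getattr(lab, "value", lab) for lab in self.labels], dtype=object)


def batch_features(windows: np.ndarray, dt_s: float) -> np.ndarray:
    """Compute the 7 features for every channel of every window.

    ``windows`` has shape (m, 9, n); the result has shape (m, 63), flattened
    channel-major so column order matches :data:`FEATURE_NAMES`.
    """
    x = np.asarray(windows, dtype=float)
    if x.ndim != 3 or x.shape[1] != len(CHANNELS):
        raise ValueError("windows must be shaped (m, 9, n)")
    n = x.shape[2]
    if n < 2:
        raise ValueError("windows must contain at least 2 samples")

    mean = x.mean(axis=-1)
    dev = x - mean[..., None]
    m2 = np.mean(dev**2, axis=-1)
    m3 = np.mean(dev**3, axis=-1)
    m4 = np.mean(dev**4, axis=-1)
    sumsq = np.sum(x**2, axis=-1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # guarded divisions on m2 == 0
        skew = np.where(m2 > 0, m3 / np.where(m2 > 0, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(m2 > 0, m4 / np.where(m2 > 0, m2, 1.0) ** 2 - 3.0, 0.0)

    feats = np.stack(
        [
            mean,                     # F1
            m2,                       # F2 population variance
            np.sqrt(sumsq / n),       # F3 RMS
            skew,                     # F4
            kurt,                     # F5 excess
            sumsq,                    # F6 energy
            np.sum(np.abs(x), axis=-1) * dt_s,  # F8 IAV
        ],
        axis=-1,
    )  # (m, 9, 7)
    return feats.reshape(x.shape[0], -1)


def extract_features(window: LabeledWindow | np.ndarray, dt_s: float) -> FeatureVector:
    """Feature vector of a single (9, n) window; ``dt_s`` is the sample period."""
    samples = window.samples if isinstance(window, LabeledWindow) else np.asarray(window)
    if samples.ndim != 2 or samples.shape[0] != len(CHANNELS):
        raise ValueError("window samples must be shaped (9, n)")
    values = batch_features(samples[None, ...], dt_s)[0]
    return FeatureVector(values=values)


def segment_windows(
    stream: SensorStream,
    labels: Sequence[tuple[float, float, BehaviorLabel]],
    spec: WindowSpec = WindowSpec(),
) -> list[LabeledWindow]:
    """Tile the stream into windows and attach strict-majority labels.

    ``labels`` are non-overlapping (start_s, end_s, behavior) intervals.
    Windows whose dominant behavior covers no more than ``min_label_coverage``
    of the window stay unlabeled (``label=None``) but are retained.
    """
    n = spec.n_samples(stream.sample_rate_hz)
    if n > stream.n_samples:
        warnings.warn("window longer than stream; no windows produced")
        return []
    step = max(1, int(round(n * (1.0 - spec.overlap_fraction))))
    intervals = sorted(labels, key=lambda iv: iv[0])
    for (a0, a1, _), (b0, _b1, _) in zip(intervals, intervals[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError("label intervals overlap")

    out: list[LabeledWindow] = []
    t0 = stream.t_s[0]
    for i0 in range(0, stream.n_samples - n + 1, step):
        ws = t0 + i0 / stream.sample_rate_hz
        we = ws + spec.length_s
        coverage: dict[BehaviorLabel, float] = {}
        for s, e, lab in intervals:
            ov = min(we, e) - max(ws, s)
            if ov > 0:
                coverage[lab] = coverage.get(lab, 0.0) + ov
        label: Optional[BehaviorLabel] = None
        if coverage:
            best = max(coverage, key=lambda k: coverage[k])
            if coverage[best] > spec.min_label_coverage * spec.length_s + 1e-9:
                label = best
        out.append(
            LabeledWindow(
                start_s=ws,
                samples=stream.data[:, i0 : i0 + n],
                label=label,
                animal_id=stream.animal_id,
            )
        )
    return out


def build_feature_matrix(
    windows: Sequence[LabeledWindow], dt_s: float
) -> FeatureMatrix:
    """One feature row per *labeled* window, ordered by (animal, start time)."""
    labeled = [w for w in windows if w.label is not None]
    if not labeled:
        raise ValueError("no labeled windows")
    labeled.sort(key=lambda w: (w.animal_id, w.start_s))
    stack = np.stack([w.samples for w in labeled])
    X = batch_features(stack, dt_s)
    return FeatureMatrix(
        X=X,
        labels=[w.label for w in labeled],
        animal_ids=[w.animal_id for w in labeled],
        start_s=np.array([w.start_s for w in labeled]),
    )
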