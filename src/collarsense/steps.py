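"""Binary-SVM step counting from collar accelerometry.

A binary RBF-SVM is trained on short-window features (the same 63-feature
representation used for behaviour classification, on 1-s windows by
default) to detect walking.  Steps are then counted inside the detected
walking spans.  Counting rules:

* ``cycles`` (default): one step per gait cycle, counted as hysteresis
  mean-crossings of the fore–aft acceleration within each detected run —
  a 1-s window cannot resolve individual steps at gait rates above 1 Hz,
  so positive windows delimit *where* walking happens and the oscillation
  itself says how many steps it contains;
* ``per_window``: one step per positive window;
* ``per_run``: one step per maximal run of positive windows.

Accuracy against ground truth uses 100·(1 − |identified − actual|/actual),
which penalises over- and under-counting symmetrically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import (
    FeatureMatrix,
    SensorStream,
    WindowSpec,
    batch_features,
    segment_windows,
)
from .labels import BehaviorLabel

#: Binary labels used by the step detector's feature matrix.
POSITIVE_LABEL = "walking"
NEGATIVE_LABEL = "other"


@dataclass
class StepWindowSpec:
    """Detector windowing and the rule mapping positive windows to steps."""

    length_s: float = 1.0
    overlap_fraction: float = 0.0
    merge_gap_windows: int = 0
    counting_rule: str = "cycles"  # cycles | per_window | per_run
    steps_per_cycle: int = 1

    def __post_init__(self) -> None:
        if self.length_s <= 0:
            raise ValueError("length_s must be positive")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.merge_gap_windows < 0:
            raise ValueError("merge_gap_windows must be nonnegative")
        if self.counting_rule not in ("cycles", "per_window", "per_run"):
            raise ValueError("counting_rule must be cycles, per_window or per_run")


@dataclass
class StepEvents:
    """Detector output on one stream."""

    window_starts_s: np.ndarray  # starts of positive windows
    step_count: int
    runs: list[tuple[float, float]]  # maximal consecutive-positive spans


@dataclass
class StepCountResult:
    animal_id: str
    identified: int
    actual: int

    @property
    def accuracy_pct(self) -> float:
        return step_accuracy(self.identified, self.actual)


@dataclass
class CohortStepReport:
    results: list[StepCountResult]
    pooled_accuracy_pct: float
    mean_accuracy_pct: float

    def to_dict(self) -> dict:
        return {
            "per_animal": [
                {
                    "animal_id": r.animal_id,
                    "identified": r.identified,
                    "actual": r.actual,
                    "accuracy_pct": r.accuracy_pct,
                }
                for r in self.results
            ],
            "pooled_accuracy_pct": self.pooled_accuracy_pct,
            "mean_accuracy_pct": self.mean_accuracy_pct,
        }


def _window_spec(spec: StepWindowSpec) -> WindowSpec:
    return WindowSpec(
        length_s=spec.length_s, overlap_fraction=spec.overlap_fraction
    )


def step_training_matrix(
    datasets: Sequence, spec: Optional[StepWindowSpec] = None
) -> FeatureMatrix:
    """Binary walking/other feature matrix from simulated (or loaded) animals.

    Each dataset needs ``stream``, ``schedule`` and ``animal_id``; a window is
    positive when walking covers its strict majority.
    """
    spec = spec or StepWindowSpec()
    rows, labels, ids, starts = [], [], [], []
    for ds in datasets:
        wins = segment_windows(ds.stream, ds.schedule.intervals(), _window_spec(spec))
        dt = 1.0 / ds.stream.sample_rate_hz
        stack = np.stack([w.samples for w in wins])
        X = batch_features(stack, dt)
        for w, x in zip(wins, X):
            rows.append(x)
            labels.append(
                POSITIVE_LABEL if w.label is BehaviorLabel.WALKING else NEGATIVE_LABEL
            )
            ids.append(ds.animal_id)
            starts.append(w.start_s)
    return FeatureMatrix(
        X=np.array(rows),
        labels=labels,
        animal_ids=ids,
        start_s=np.array(starts),
    )


def train_step_detector(
    matrix: FeatureMatrix,
    hyperparams: Optional[Mapping] = None,
    seed: int = 0,
    max_per_class: int = 3000,
):
    """Fit the binary walking detector (z-scored RBF SVM).

    Training rows are capped at ``max_per_class`` per class (seeded balanced
    subsample) so kernel training stays tractable on long recordings.
    """
    hp = dict(hyperparams or {})
    y = np.asarray([getattr(lab, "value", lab) for lab in matrix.labels])
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("step-detector training needs both classes present")
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in classes:
        idx = np.where(y == c)[0]
        if idx.size > max_per_class:
            idx = np.sort(rng.choice(idx, size=max_per_class, replace=False))
        keep.append(idx)
    sel = np.sort(np.concatenate(keep))
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svm",
                SVC(
                    kernel=hp.pop("kernel", "rbf"),
                    C=hp.pop("C", 10.0),
                    gamma=hp.pop("gamma", "scale"),
                    random_state=seed,
                    **hp,
                ),
            ),
        ]
    )
    model.fit(matrix.X[sel], y[sel])
    return model


def _count_cycles(x: np.ndarray) -> int:
    """Gait cycles in a detected walking span: hysteresis mean-crossings.

    The fore–aft signal is mean-detrended and lightly smoothed; a cycle is a
    rise from below −θ to above +θ with θ = half the span's RMS, which
    ignores sensor noise in the partial windows at the span's edges.
    """
    x = x - x.mean()
    if x.size >= 5:  # 3-sample smoothing: well under half a gait period
        x = np.convolve(x, np.ones(3) / 3.0, mode="same")
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        return 0
    theta = 0.5 * rms
    count = 0
    armed = True
    for v in x:
        if v < -theta:
            armed = True
        elif v > theta and armed:
            count += 1
            armed = False
    return count


def count_steps(
    detector, stream: SensorStream, spec: Optional[StepWindowSpec] = None
) -> StepEvents:
    """Classify windows with the detector and count steps per the configured rule."""
    spec = spec or StepWindowSpec()
    n = int(round(spec.length_s * stream.sample_rate_hz))
    if n > stream.n_samples:
        warnings.warn("stream shorter than one window; zero step events")
        return StepEvents(np.array([]), 0, [])
    wins = segment_windows(stream, [], _window_spec(spec))
    dt = 1.0 / stream.sample_rate_hz
    X = batch_features(np.stack([w.samples for w in wins]), dt)
    pred = detector.predict(X)
    positive = np.asarray(pred) == POSITIVE_LABEL
    starts = np.array([w.start_s for w in wins])

    # maximal runs of positive windows, optionally merging short gaps
    runs_idx: list[tuple[int, int]] = []
    i = 0
    while i < positive.size:
        if positive[i]:
            j = i
            while j + 1 < positive.size and positive[j + 1]:
                j += 1
            runs_idx.append((i, j))
            i = j + 1
        else:
            i += 1
    if spec.merge_gap_windows > 0 and runs_idx:
        merged = [runs_idx[0]]
        for a, b in runs_idx[1:]:
            if a - merged[-1][1] - 1 <= spec.merge_gap_windows:
                merged[-1] = (merged[-1][0], b)
            else:
                merged.append((a, b))
        runs_idx = merged

    runs = [(starts[a], starts[b] + spec.length_s) for a, b in runs_idx]

    if spec.counting_rule == "per_window":
        step_count = int(positive.sum())
    elif spec.counting_rule == "per_run":
        step_count = len(runs_idx)
    else:  # cycles
        step_count = 0
        ax = stream.data[0]
        t0 = stream.t_s[0]
        fs = stream.sample_rate_hz
        for a, b in runs_idx:
            i0 = int(round((starts[a] - t0) * fs))
            i1 = int(round((starts[b] + spec.length_s - t0) * fs))
            step_count += spec.steps_per_cycle * _count_cycles(ax[i0:i1])

    return StepEvents(
        window_starts_s=starts[positive], step_count=step_count, runs=runs
    )


def step_accuracy(identified: int, actual: int) -> float:
    """100·(1 − |identified − actual| / actual); symmetric in the error sign."""
    if actual <= 0:
        raise ValueError("actual step count must be positive")
    if identified < 0:
        raise ValueError("identified step count must be nonnegative")
    return 100.0 * (1.0 - abs(identified - actual) / actual)


def cohort_step_report(results: Sequence[StepCountResult]) -> CohortStepReport:
    """Pooled accuracy from summed counts; mean as the unweighted per-animal mean."""
    results = list(results)
    if not results:
        raise ValueError("no step-count results")
    pooled = step_accuracy(
        sum(r.identified for r in results), sum(r.actual for r in results)
    )
    mean = float(np.mean([r.accuracy_pct for r in results]))
    return CohortStepReport(
        results=results, pooled_accuracy_pct=pooled, mean_accuracy_pct=mean
    )
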