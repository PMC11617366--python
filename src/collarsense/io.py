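"""CSV exchange formats for streams, temperature traces, labels and features.

All artifacts are plain CSV with float seconds from recording start:

* sensor stream: ``t_s, ax_g, ay_g, az_g, gx_dps, gy_dps, gz_dps, mx, my, mz``
* temperature:   ``t_s, temp_c``
* labels:        ``start_s, end_s, behavior``
* steps:         ``t_s``
* features:      ``animal_id, start_s, label, ax_F1 … mz_F8``
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import (
    CHANNEL_COLUMNS,
    FEATURE_NAMES,
    FeatureMatrix,
    SensorStream,
)
from .labels import BehaviorLabel
from .temperature import TemperatureTrace

_FLOAT_FMT = "%.9g"


def write_sensor_csv(stream: SensorStream, path) -> None:
    df = pd.DataFrame({"t_s": stream.t_s})
    for col, row in zip(CHANNEL_COLUMNS, stream.data):
        df[col] = row
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sensor_csv(path, animal_id: str = "") -> SensorStream:
    """Load a stream, inferring the sample rate from the timestamps."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty sensor file")
    missing = [c for c in ("t_s",) + CHANNEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if df.isna().any().any():
        raise ValueError(f"{path}: NaN values present")
    t = df["t_s"].to_numpy(float)
    dt = np.diff(t)
    if t.size < 2 or np.any(dt <= 0):
        raise ValueError(f"{path}: timestamps must be strictly increasing")
    rate = 1.0 / float(np.median(dt))
    data = df[list(CHANNEL_COLUMNS)].to_numpy(float).T
    return SensorStream(t_s=t, data=data, sample_rate_hz=rate, animal_id=animal_id)


def write_temperature_csv(trace: TemperatureTrace, path) -> None:
    pd.DataFrame({"t_s": trace.t_s, "temp_c": trace.temp_c}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_temperature_csv(
    path, rectal_baseline_c: Optional[float] = None, animal_id: str = ""
) -> TemperatureTrace:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty temperature file")
    for c in ("t_s", "temp_c"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    return TemperatureTrace(
        t_s=df["t_s"].to_numpy(float),
        temp_c=df["temp_c"].to_numpy(float),
        rectal_baseline_c=rectal_baseline_c,
        animal_id=animal_id,
    )


def write_labels_csv(
    intervals: Sequence[tuple[float, float, BehaviorLabel]], path
) -> None:
    pd.DataFrame(
        [(s, e, lab.value) for s, e, lab in intervals],
        columns=["start_s", "end_s", "behavior"],
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_label_csv(path) -> list[tuple[float, float, BehaviorLabel]]:
    """Load label intervals; validates non-overlap and the behavior vocabulary."""
    df = pd.read_csv(path)
    for c in ("start_s", "end_s", "behavior"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c}")
    out = [
        (float(r.start_s), float(r.end_s), BehaviorLabel.parse(str(r.behavior)))
        for r in df.itertuples()
    ]
    out.sort(key=lambda iv: iv[0])
    for (_, e0, _), (s1, _, _) in zip(out, out[1:]):
        if s1 < e0 - 1e-9:
            raise ValueError(f"{path}: overlapping label intervals")
    return out


def write_steps_csv(times_s: np.ndarray, path) -> None:
    pd.DataFrame({"t_s": np.asarray(times_s, float)}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_steps_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "t_s" not in df.columns:
        raise ValueError(f"{path}: missing column t_s")
    return df["t_s"].to_numpy(float)


def write_feature_csv(matrix: FeatureMatrix, path) -> None:
    df = pd.DataFrame(matrix.X, columns=list(matrix.feature_names))
    df.insert(0, "label", [getattr(l, "value", l) for l in matrix.labels])
    df.insert(0, "start_s", matrix.start_s)
    df.insert(0, "animal_id", matrix.animal_ids)
    df.to_csv(path, index=False, float_format="%.12g")


def read_feature_csv(path) -> FeatureMatrix:
    df = pd.read_csv(path)
    meta = ("animal_id", "start_s", "label")
    missing = [c for c in meta if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    feat_cols = [c for c in df.columns if c not in meta]
    if tuple(feat_cols) != FEATURE_NAMES:
        raise ValueError(f"{path}: unexpected feature columns")
    return FeatureMatrix(
        X=df[feat_cols].to_numpy(float),
        labels=[str(l) for l in df["label"]],
        animal_ids=[str(a) for a in df["animal_id"]],
        start_s=df["start_s"].to_numpy(float),
    )


def write_dataset(dataset, out_dir) -> dict[str, str]:
    """Write one animal's bundle (IMU, temperature, labels, steps) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aid = dataset.animal_id
    paths = {
        "imu": out / f"{aid}_imu.csv",
        "temperature": out / f"{aid}_temp.csv",
        "labels": out / f"{aid}_labels.csv",
        "steps": out / f"{aid}_steps.csv",
    }
    write_sensor_csv(dataset.stream, paths["imu"])
    write_temperature_csv(dataset.temperature, paths["temperature"])
    write_labels_csv(dataset.schedule.intervals(), paths["labels"])
    write_steps_csv(dataset.true_step_times_s, paths["steps"])
    return {k: str(v) for k, v in paths.items()}
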