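"""Seeded simulator for collar-sensor recordings of housed cattle.

The generator produces everything the analysis pipeline consumes:

* a **behaviour schedule** from a semi-Markov chain over the five sustained
  behaviours (exponential dwell times with behaviour-specific means), with
  every stand↔lie posture change bridged by the matching transition class;
* a **9-channel IMU stream** whose per-sample model is
  ``gravity orientation for the posture + behaviour component + noise`` —
  a periodic gait oscillation while walking (one ground-truth step per gait
  cycle), a slow head-bob while grazing/feeding, pure noise at rest, and a
  linear orientation ramp during posture transitions;
* a **skin-temperature trace**: baseline below the rectal reference plus a
  slow sinusoidal drift, AR(1) noise and Poisson-placed artifact spikes;
* per-animal bundles for a whole cohort, each animal on its own child seed.

The collar frame follows the upright convention: standing posture puts
gravity on +z (az ≈ +1 g); lying rotates gravity 90° about x onto +y.
Head-down postures (grazing, and mildly feeding) pitch the collar about x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import CHANNELS, SensorStream
from .labels import (
    LABEL_ORDER,
    MAIN_LABELS,
    BehaviorLabel,
    is_lying,
)
from .temperature import TemperatureTrace

# Collar pitch (degrees about x) of each sustained behaviour's posture.
_PITCH_DEG = {
    BehaviorLabel.FEEDING: 15.0,
    BehaviorLabel.GRAZING: 40.0,
    BehaviorLabel.WALKING: 0.0,
    BehaviorLabel.LYING_RESTING: 90.0,
    BehaviorLabel.STANDING_RESTING: 0.0,
}

_MAG_HEADING = np.array([0.3, 0.1, 0.45])  # constant heading term, arbitrary units


def default_transition_matrix() -> np.ndarray:
    """Row-stochastic 7×7 matrix in :data:`~collarsense.labels.LABEL_ORDER`.

    The two transition-class rows route deterministically to the posture they
    end in; the scheduler inserts those classes itself, so these rows only
    matter for validation.
    """
    f, g, w, ly, st, s2l, l2s = range(7)
    M = np.zeros((7, 7))
    M[f, [g, w, ly, st]] = [0.3, 0.3, 0.2, 0.2]
    M[g, [f, w, ly, st]] = [0.3, 0.3, 0.2, 0.2]
    M[w, [f, g, ly, st]] = [0.25, 0.25, 0.2, 0.3]
    M[ly, [f, g, w, st]] = [0.2, 0.2, 0.2, 0.4]
    M[st, [f, g, w, ly]] = [0.25, 0.25, 0.3, 0.2]
    M[s2l, ly] = 1.0
    M[l2s, st] = 1.0
    return M


def default_dwell_means() -> dict[BehaviorLabel, float]:
    """Mean bout durations (s) for the sustained behaviours."""
    return {
        BehaviorLabel.FEEDING: 300.0,
        BehaviorLabel.GRAZING: 300.0,
        BehaviorLabel.WALKING: 90.0,
        BehaviorLabel.LYING_RESTING: 600.0,
        BehaviorLabel.STANDING_RESTING: 240.0,
    }


@dataclass
class SimConfig:
    """All knobs of the simulator; defaults are the package's study conditions.

    Rates are in Hz, accelerations in g, angular rates in degrees/s,
    temperatures in °C, durations in seconds.
    """

    sampling_rate_hz: float = 20.0
    temp_rate_hz: float = 1.0
    gait_frequency_hz: float = 1.5
    gait_amplitude_g: float = 0.4
    rest_noise_g: float = 0.02
    imu_noise_g: float = 0.05
    headbob_frequency_hz: float = 0.35
    headbob_amplitude_g: float = 0.12
    gyro_noise_dps: float = 0.5
    mag_noise: float = 0.02
    rectal_baseline_c: float = 38.3
    skin_offset_c: float = 1.1
    temp_noise_sd_c: float = 0.15
    temp_ar_coef: float = 0.9
    drift_amplitude_c: float = 0.1
    drift_period_s: float = 3600.0
    artifact_rate_per_min: float = 0.5
    artifact_magnitude_c: float = 1.0
    transition_duration_s: float = 3.0
    min_dwell_s: float = 10.0
    steps_per_cycle: int = 1  # set 2 to count each leg's pulse separately
    dwell_mean_s: dict[BehaviorLabel, float] = field(default_factory=default_dwell_means)
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        for name in (
            "sampling_rate_hz", "temp_rate_hz", "gait_frequency_hz",
            "headbob_frequency_hz", "transition_duration_s", "drift_period_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "gait_amplitude_g", "rest_noise_g", "imu_noise_g",
            "temp_noise_sd_c", "artifact_rate_per_min", "headbob_amplitude_g",
            "gyro_noise_dps", "mag_noise", "drift_amplitude_c", "min_dwell_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        M = self.transition_matrix
        if M.shape != (7, 7):
            raise ValueError("transition_matrix must be 7×7")
        if np.any(M < 0) or np.any(np.abs(M.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition_matrix rows must be nonnegative and sum to 1")
        missing = [b for b in MAIN_LABELS if b not in self.dwell_mean_s]
        if missing:
            raise ValueError(f"dwell_mean_s missing behaviours: {missing}")


@dataclass
class BehaviorSchedule:
    """Contiguous, non-overlapping (start_s, end_s, label) segments covering
    [0, total_duration_s)."""

    segments: list[tuple[float, float, BehaviorLabel]]
    total_duration_s: float

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("empty schedule")
        prev_end = 0.0
        for s, e, _lab in self.segments:
            if abs(s - prev_end) > 1e-9 or e <= s:
                raise ValueError("segments must be contiguous and increasing")
            prev_end = e
        if abs(prev_end - self.total_duration_s) > 1e-9:
            raise ValueError("segments do not cover the full duration")

    def label_at(self, t: float) -> BehaviorLabel:
        for s, e, lab in self.segments:
            if s <= t < e:
                return lab
        return self.segments[-1][2]

    def intervals(self) -> list[tuple[float, float, BehaviorLabel]]:
        return list(self.segments)


@dataclass
class SyntheticDataset:
    """One animal's bundle: IMU stream, temperature, schedule and true steps."""

    stream: SensorStream
    temperature: TemperatureTrace
    schedule: BehaviorSchedule
    true_step_times_s: np.ndarray
    animal_id: str


def _main_stationary(M: np.ndarray) -> np.ndarray:
    """Stationary distribution of the chain restricted to the 5 main states."""
    sub = M[:5, :5].copy()
    rows = sub.sum(axis=1)
    if np.any(rows <= 0):
        raise ValueError("transition_matrix has a main state with no main successor")
    sub /= rows[:, None]
    pi = np.full(5, 0.2)
    for _ in range(200):
        pi = pi @ sub
        pi /= pi.sum()
    return pi


def generate_schedule(
    config: SimConfig, duration_s: float, seed: Optional[int] = None
) -> BehaviorSchedule:
    """Semi-Markov behaviour schedule over ``[0, duration_s)``.

    Dwell times are exponential with behaviour-specific means (floored at
    ``min_dwell_s``); successive states follow the transition matrix
    restricted to the five sustained behaviours, and every stand↔lie change
    inserts the matching 3-s transition class.  Deterministic for a fixed
    seed.  Adjacent same-label segments are merged.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    M = config.transition_matrix
    pi = _main_stationary(M)
    state = MAIN_LABELS[rng.choice(5, p=pi)]

    raw: list[tuple[float, BehaviorLabel]] = []  # (length, label)
    t = 0.0
    while t < duration_s - 1e-9:
        dwell = max(rng.exponential(config.dwell_mean_s[state]), config.min_dwell_s)
        dwell = min(dwell, duration_s - t)
        raw.append((dwell, state))
        t += dwell
        if t >= duration_s - 1e-9:
            break
        row = M[LABEL_ORDER.index(state), :5].copy()
        if row.sum() <= 0:
            raise ValueError("transition_matrix gives current state no successor")
        nxt = MAIN_LABELS[rng.choice(5, p=row / row.sum())]
        if is_lying(nxt) != is_lying(state):
            bridge = (
                BehaviorLabel.STAND_TO_LIE if is_lying(nxt) else BehaviorLabel.LIE_TO_STAND
            )
            tlen = min(config.transition_duration_s, duration_s - t)
            raw.append((tlen, bridge))
            t += tlen
        state = nxt

    # merge adjacent same-label runs, then lay out contiguous segments
    merged: list[tuple[float, BehaviorLabel]] = []
    for length, lab in raw:
        if merged and merged[-1][1] is lab:
            merged[-1] = (merged[-1][0] + length, lab)
        else:
            merged.append((length, lab))
    segments: list[tuple[float, float, BehaviorLabel]] = []
    t = 0.0
    for length, lab in merged:
        segments.append((t, t + length, lab))
        t += length
    # close any floating-point shortfall on the last segment
    s, _e, lab = segments[-1]
    segments[-1] = (s, duration_s, lab)
    return BehaviorSchedule(segments=segments, total_duration_s=duration_s)


def _segment_pitches(schedule: BehaviorSchedule) -> list[tuple[float, float]]:
    """(pitch_start, pitch_end) in radians per segment; transitions ramp."""
    segs = schedule.segments
    out: list[tuple[float, float]] = []
    for i, (_s, _e, lab) in enumerate(segs):
        if lab in _PITCH_DEG:
            p = math.radians(_PITCH_DEG[lab])
            out.append((p, p))
        else:
            prev = segs[i - 1][2] if i > 0 else BehaviorLabel.STANDING_RESTING
            nxt = segs[i + 1][2] if i + 1 < len(segs) else BehaviorLabel.STANDING_RESTING
            p0 = math.radians(_PITCH_DEG.get(prev, 0.0))
            p1 = math.radians(_PITCH_DEG.get(nxt, 90.0))
            out.append((p0, p1))
    return out


def synthesize_imu(
    schedule: BehaviorSchedule, config: SimConfig, seed: Optional[int] = None
) -> tuple[SensorStream, np.ndarray]:
    """Render the schedule into a 9-channel IMU stream plus true step times.

    Deterministic model per segment (local time τ, pitch θ):

    * gravity: ``a = (0, sinθ, cosθ)`` g — standing θ=0, lying θ=90°,
      grazing 40°, feeding 15°; transitions ramp θ linearly.
    * walking: fore–aft ``ax += A·sin(2πfτ)`` and vertical
      ``az += 0.5A·cos(2πfτ)`` at the gait frequency; one true step per
      cycle at τ = k/f; pitch rate ``gx = 15·sin(2πfτ)`` dps.
    * grazing: ``ax += h·sin(2π f_bob τ)``, ``gx = 4·sin(2π f_bob τ)``.
    * feeding: ``ax += 1.5h·sin(2π f_bob τ)`` with a lateral sway
      ``ay += 0.8h·sin(2π·0.6·f_bob·τ)``; ``gx = 6·sin(2π f_bob τ)``.
    * transitions: ``gx`` equals the constant pitch rate of the ramp.
    * rest classes: gravity only.

    Gaussian noise: accel sd ``rest_noise_g`` at rest else ``imu_noise_g``;
    gyro sd ``gyro_noise_dps``; magnetometer = constant heading + ``mag_noise``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.sampling_rate_hz
    n = int(round(schedule.total_duration_s * fs))
    if n == 0:
        raise ValueError("schedule too short for one sample")
    t = np.arange(n) / fs
    data = np.zeros((len(CHANNELS), n))
    ax, ay, az, gx = data[0], data[1], data[2], data[3]

    pitches = _segment_pitches(schedule)
    step_times: list[float] = []
    f_gait, f_bob = config.gait_frequency_hz, config.headbob_frequency_hz
    A, h = config.gait_amplitude_g, config.headbob_amplitude_g

    for (s, e, lab), (p0, p1) in zip(schedule.segments, pitches):
        idx = slice(int(np.ceil(s * fs - 1e-9)), int(np.ceil(e * fs - 1e-9)))
        tau = t[idx] - s
        dur = e - s
        theta = p0 + (p1 - p0) * (tau / dur)
        ay[idx] += np.sin(theta)
        az[idx] += np.cos(theta)
        if lab is BehaviorLabel.WALKING:
            ax[idx] += A * np.sin(2 * np.pi * f_gait * tau)
            az[idx] += 0.5 * A * np.cos(2 * np.pi * f_gait * tau)
            gx[idx] += 15.0 * np.sin(2 * np.pi * f_gait * tau)
            f_step = f_gait * config.steps_per_cycle
            k_max = int(math.floor(dur * f_step + 1e-9))
            step_times.extend(s + k / f_step for k in range(1, k_max + 1))
        elif lab is BehaviorLabel.GRAZING:
            ax[idx] += h * np.sin(2 * np.pi * f_bob * tau)
            gx[idx] += 4.0 * np.sin(2 * np.pi * f_bob * tau)
        elif lab is BehaviorLabel.FEEDING:
            ax[idx] += 1.5 * h * np.sin(2 * np.pi * f_bob * tau)
            ay[idx] += 0.8 * h * np.sin(2 * np.pi * 0.6 * f_bob * tau)
            gx[idx] += 6.0 * np.sin(2 * np.pi * f_bob * tau)
        elif lab not in _PITCH_DEG:  # posture transition: constant pitch rate
            gx[idx] += math.degrees(p1 - p0) / dur

        sd = config.rest_noise_g if lab in (
            BehaviorLabel.LYING_RESTING, BehaviorLabel.STANDING_RESTING
        ) else config.imu_noise_g
        m = tau.size
        data[0:3, idx] += rng.normal(0.0, sd, size=(3, m)) if sd > 0 else 0.0
        if config.gyro_noise_dps > 0:
            data[3:6, idx] += rng.normal(0.0, config.gyro_noise_dps, size=(3, m))

    data[6:9] += _MAG_HEADING[:, None]
    if config.mag_noise > 0:
        data[6:9] += rng.normal(0.0, config.mag_noise, size=(3, n))

    stream = SensorStream(t_s=t, data=data, sample_rate_hz=fs)
    return stream, np.array(sorted(step_times))


def synthesize_temperature(
    config: SimConfig, duration_s: float, seed: Optional[int] = None
) -> TemperatureTrace:
    """Skin-temperature trace: baseline + slow drift + AR(1) noise + artifacts.

    The mean level sits ``skin_offset_c`` below the rectal baseline; drift is
    a sinusoid of amplitude ``drift_amplitude_c`` and period ``drift_period_s``;
    AR(1) noise has stationary sd ``temp_noise_sd_c``; artifact spikes arrive
    as a Poisson process (``artifact_rate_per_min``), last 1–3 samples and
    deflect by ±``artifact_magnitude_c``.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = max(2, int(round(duration_s * config.temp_rate_hz)))
    t = np.arange(n) / config.temp_rate_hz
    base = config.rectal_baseline_c - config.skin_offset_c
    drift = config.drift_amplitude_c * np.sin(2 * np.pi * t / config.drift_period_s)

    noise = np.zeros(n)
    if config.temp_noise_sd_c > 0:
        phi = config.temp_ar_coef
        innov_sd = config.temp_noise_sd_c * math.sqrt(1.0 - phi**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        noise[0] = rng.normal(0.0, config.temp_noise_sd_c)
        for i in range(1, n):
            noise[i] = phi * noise[i - 1] + eps[i]

    temp = base + drift + noise
    n_art = rng.poisson(config.artifact_rate_per_min * duration_s / 60.0)
    for _ in range(n_art):
        i0 = int(rng.integers(0, n))
        width = int(rng.integers(1, 4))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        temp[i0 : i0 + width] += sign * config.artifact_magnitude_c

    return TemperatureTrace(
        t_s=t, temp_c=temp, rectal_baseline_c=config.rectal_baseline_c
    )


def generate_dataset(
    config: SimConfig, duration_s: float, seed: int, animal_id: str = "C1"
) -> SyntheticDataset:
    """One animal's full bundle; child seeds are fixed offsets of ``seed``."""
    schedule = generate_schedule(config, duration_s, seed=seed)
    stream, steps = synthesize_imu(schedule, config, seed=seed + 10_000)
    stream.animal_id = animal_id
    temperature = synthesize_temperature(config, duration_s, seed=seed + 20_000)
    temperature.animal_id = animal_id
    return SyntheticDataset(
        stream=stream,
        temperature=temperature,
        schedule=schedule,
        true_step_times_s=steps,
        animal_id=animal_id,
    )


def generate_cohort(
    n_animals: int,
    config: SimConfig = SimConfig(),
    duration_s: float = 3 * 3600.0,
    base_seed: int = 0,
) -> list[SyntheticDataset]:
    """Cohort of ``n_animals`` datasets; animal *i* uses seed ``base_seed + i``
    and id ``C{i}`` (1-based)."""
    if n_animals < 1:
        raise ValueError("n_animals must be ≥ 1")
    return [
        generate_dataset(config, duration_s, seed=base_seed + i, animal_id=f"C{i}")
        for i in range(1, n_animals + 1)
    ]
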