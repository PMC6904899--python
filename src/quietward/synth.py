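"""Synthetic vital-sign streams with episodic anomalies.

Real intraoperative monitoring traces are dominated by long stretches of
in-range values punctuated by contiguous multi-minute excursions; sampled
once per second, a single excursion produces hundreds of per-second alarms
that the notification reasoner collapses into a handful of deliveries.
The generator reproduces exactly that structure and nothing more: a
Gaussian baseline clipped strictly inside the normal range, overlaid with
rectangular anomalous episodes held a fixed magnitude beyond the violated
threshold (plus bounded jitter that can never cross back into range).
Physiological dynamics — heart-rate variability, trends, artifacts — are
deliberately out of scope; the contract is "this many anomalous samples,
in these windows", which is what the notification arithmetic depends on.

:func:`make_experiment_fixture` packages the five reference monitoring
scenarios: one patient, one heart-rate sensor at 1 Hz, 60,000 readings,
per-patient thresholds, a 5-minute minimum notification interval, and an
episode layout whose anomalous seconds reproduce the published alarm and
notification counts for that scenario.  The true temporal positions of
the original episodes are unpublished, so the layouts are count-faithful
synthetic stand-ins, not waveform reconstructions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .events import (
    Direction,
    ExperimentConfig,
    NotificationPolicy,
    Reading,
    ThresholdConfig,
)

__all__ = [
    "EpisodeSpec",
    "StreamSpec",
    "generate_stream",
    "write_stream",
    "readings_from_frame",
    "make_experiment_fixture",
    "TABLE_THRESHOLDS",
    "EXPERIMENT_ALARM_COUNTS",
    "EXPERIMENT_NOTIFICATION_COUNTS",
    "MNI_MS",
]

#: per-experiment heart-rate thresholds (experiment id -> (v_min, v_max));
#: patient id equals the experiment id in the reference setup
TABLE_THRESHOLDS: dict[int, tuple[float, float]] = {
    1: (60.0, 100.0),
    2: (55.0, 100.0),
    3: (50.0, 105.0),
    4: (50.0, 100.0),
    5: (50.0, 102.0),
}

#: total anomalous seconds (= alarms at 1 Hz) per reference experiment
EXPERIMENT_ALARM_COUNTS: dict[int, int] = {1: 407, 2: 423, 3: 308, 4: 586, 5: 204}

#: notifications each reference experiment must collapse to
EXPERIMENT_NOTIFICATION_COUNTS: dict[int, int] = {1: 4, 2: 3, 3: 3, 4: 4, 5: 2}

#: minimum notification interval of the reference setup: 5 minutes
MNI_MS = 300_000

# Episode layouts in (start_s, duration_s).  A contiguous run of n >= 2
# per-second alarms starting from an idle key yields
# 1 + ceil((n-1)*1000/MNI) notifications (one immediate + the grouped
# releases), so runs of 2..301 s yield 2 and runs of 302..601 s yield 3.
# Runs are separated by far more than one MNI so each starts idle.
_EPISODE_LAYOUTS: dict[int, list[tuple[int, int]]] = {
    1: [(600, 207), (3600, 200)],  # 2 + 2 notifications
    2: [(600, 423)],               # 3 notifications
    3: [(600, 308)],               # 3 notifications
    4: [(600, 293), (3600, 293)],  # 2 + 2 notifications
    5: [(600, 204)],               # 2 notifications
}


@dataclass(frozen=True)
class EpisodeSpec:
    """One contiguous anomalous excursion.

    ``magnitude`` is how far beyond the violated threshold the episode
    sits, in sensor units; jitter stays within half a magnitude so the
    values never re-enter the normal range.
    """

    start: int        # ms from stream epoch
    duration: int     # ms
    direction: Direction
    magnitude: float  # sensor units beyond the threshold

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("episode duration must be positive")
        if self.magnitude <= 0:
            raise ValueError("episode magnitude must be positive")
        if self.direction not in (Direction.LOW, Direction.HIGH):
            raise ValueError("episode direction must be low or high")

    @property
    def end(self) -> int:
        return self.start + self.duration


@dataclass(frozen=True)
class StreamSpec:
    """Recipe for one deterministic synthetic stream."""

    patient_id: str
    sensor_type: str
    baseline_mean: float
    baseline_sd: float
    interval: int      # ms between readings
    n_readings: int
    episodes: tuple[EpisodeSpec, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise ValueError("baseline_sd must be >= 0")
        if self.interval <= 0 or self.n_readings <= 0:
            raise ValueError("interval and n_readings must be positive")

    @property
    def horizon(self) -> int:
        """Total stream span in ms (one reading every ``interval``)."""
        return self.n_readings * self.interval


class SpecError(ValueError):
    """StreamSpec inconsistent with the thresholds it must respect."""


def _validate(spec: StreamSpec, thresholds: ThresholdConfig) -> None:
    if not (thresholds.v_min < spec.baseline_mean < thresholds.v_max):
        raise SpecError(
            f"baseline_mean={spec.baseline_mean} must lie strictly inside "
            f"({thresholds.v_min}, {thresholds.v_max})"
        )
    for ep in spec.episodes:
        if ep.start < 0 or ep.end > spec.horizon:
            raise SpecError(
                f"episode [{ep.start}, {ep.end}) outside the stream horizon "
                f"[0, {spec.horizon})"
            )


def generate_stream(spec: StreamSpec, thresholds: ThresholdConfig) -> pd.DataFrame:
    """Generate a reading stream as a DataFrame (time_ms, patient_id, sensor_type, value).

    Readings sit at t = 0, interval, 2*interval, ...  A reading at t falls
    inside an episode iff start <= t < start + duration; its value is the
    violated threshold plus/minus the episode magnitude with uniform
    jitter in [-magnitude/2, +magnitude/2], so it is always anomalous.
    Out-of-episode values are Gaussian around the baseline, clipped
    strictly inside the normal range, so they are never anomalous.
    Identical specs (including the seed) generate identical frames.
    """
    _validate(spec, thresholds)
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.n_readings, dtype=np.int64) * spec.interval

    span = thresholds.v_max - thresholds.v_min
    margin = min(1.0, span / 10.0)
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=spec.n_readings)
    values = np.clip(baseline, thresholds.v_min + margin, thresholds.v_max - margin)

    jitter = rng.uniform(-0.5, 0.5, size=spec.n_readings)
    for ep in spec.episodes:
        mask = (times >= ep.start) & (times < ep.end)
        if ep.direction is Direction.HIGH:
            values[mask] = thresholds.v_max + ep.magnitude + jitter[mask] * ep.magnitude
        else:
            values[mask] = thresholds.v_min - ep.magnitude + jitter[mask] * ep.magnitude

    return pd.DataFrame(
        {
            "time_ms": times,
            "patient_id": spec.patient_id,
            "sensor_type": spec.sensor_type,
            "value": np.round(values, 3),
        }
    )


def write_stream(spec: StreamSpec, thresholds: ThresholdConfig, path) -> None:
    """Generate and write a stream CSV; identical seeds give identical bytes."""
    generate_stream(spec, thresholds).to_csv(path, index=False, lineterminator="\n")


def readings_from_frame(df: pd.DataFrame) -> list[Reading]:
    """Convert a generated frame to Reading objects without a CSV round trip."""
    return [
        Reading(
            patient_id=str(row.patient_id),
            sensor_type=str(row.sensor_type),
            value=float(row.value),
            time=int(row.time_ms),
        )
        for row in df.itertuples(index=False)
    ]


def make_experiment_fixture(
    experiment_id: int, *, seed: Optional[int] = None
) -> tuple[ExperimentConfig, StreamSpec]:
    """Build the configuration and stream recipe for a reference experiment.

    Scenario scaffold: 1 ward, 1 patient (id = experiment id), 1 heart-rate
    sensor read every 1000 ms for 60,000 readings, the per-patient
    thresholds, and a 5-minute MNI.  The episode layout places the
    experiment's anomalous seconds into high-side excursions positioned so
    the replay collapses them to the published notification count.  The
    seed only perturbs baseline noise and in-episode jitter, never the
    alarm count.
    """
    if experiment_id not in TABLE_THRESHOLDS:
        raise ValueError(f"experiment_id must be 1..5, got {experiment_id}")
    v_min, v_max = TABLE_THRESHOLDS[experiment_id]
    patient_id = str(experiment_id)
    threshold = ThresholdConfig(
        patient_id=patient_id,
        sensor_type="heart_rate",
        v_min=v_min,
        v_max=v_max,
    )
    cfg = ExperimentConfig(
        number_of_wards=1,
        number_of_patients=1,
        number_of_sensors=1,
        sensors_reading_interval=1000,
        number_of_readings=60_000,
        thresholds={threshold.key: threshold},
        policy=NotificationPolicy(mni=MNI_MS, d_beta_default=0),
    )
    episodes = tuple(
        EpisodeSpec(
            start=start_s * 1000,
            duration=duration_s * 1000,
            direction=Direction.HIGH,
            magnitude=15.0,
        )
        for start_s, duration_s in _EPISODE_LAYOUTS[experiment_id]
    )
    assert sum(ep.duration for ep in episodes) // 1000 == EXPERIMENT_ALARM_COUNTS[experiment_id]
    spec = StreamSpec(
        patient_id=patient_id,
        sensor_type="heart_rate",
        baseline_mean=(v_min + v_max) / 2.0,
        baseline_sd=5.0,
        interval=1000,
        n_readings=60_000,
        episodes=episodes,
        seed=seed if seed is not None else 1_000 + experiment_id,
    )
    return cfg, spec
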