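"""Threshold-based anomaly detection and alarm triggering.

A reading is anomalous for its (patient, sensor) pair iff strictly outside
the configured normal range: value < v_min or value > v_max.  Values equal
to a limit are normal.  Every anomalous reading raises its own anomaly and
alarm — there is no run-length merging at detection time, so a 5-minute
episode sampled at 1 Hz yields 300 alarms.

Also provides the stream readers: the canonical per-reading CSV
(``time_ms,patient_id,sensor_type,value``) and a convenience routing-key
format (``<patientID>.<value>`` per line) for heart-rate-only streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import pandas as pd

from .events import (
    AlarmEvent,
    AnomalyEvent,
    Direction,
    ExperimentConfig,
    NotificationPolicy,
    Reading,
    StreamParseError,
    ThresholdConfig,
)

__all__ = [
    "DetectionOutcome",
    "is_anomalous",
    "detect",
    "trigger_alarm",
    "read_stream",
    "read_routing_key_stream",
]


@dataclass(frozen=True)
class DetectionOutcome:
    """Result of evaluating one reading against its thresholds."""

    reading: Reading
    anomalous: bool
    direction: Direction

    def __post_init__(self) -> None:
        if self.anomalous != (self.direction is not Direction.NONE):
            raise ValueError("anomalous flag must match direction")


def is_anomalous(value: float, threshold: ThresholdConfig) -> tuple[bool, Direction]:
    """Decide whether ``value`` is anomalous under ``threshold``.

    Strict comparisons on both sides: anomalous iff value < v_min or
    value > v_max.  Returns (anomalous, direction).
    """
    if not math.isfinite(value):
        raise ValueError(f"cannot evaluate non-finite value {value!r}")
    if value < threshold.v_min:
        return True, Direction.LOW
    if value > threshold.v_max:
        return True, Direction.HIGH
    return False, Direction.NONE


def detect(reading: Reading, cfg: ExperimentConfig) -> Optional[AnomalyEvent]:
    """Evaluate one reading; return an anomaly event or None.

    Non-anomalous readings are ignored (the monitor only forwards
    out-of-range values to the reasoner).  A missing threshold for the
    reading's (patient, sensor) pair is a configuration error.
    """
    threshold = cfg.threshold_for(reading.patient_id, reading.sensor_type)
    anomalous, direction = is_anomalous(reading.value, threshold)
    if not anomalous:
        return None
    return AnomalyEvent(
        patient_id=reading.patient_id,
        sensor_type=reading.sensor_type,
        value=reading.value,
        t_alpha=reading.time,
        direction=direction,
    )


def trigger_alarm(
    anomaly: AnomalyEvent, policy: NotificationPolicy, alarm_id: int
) -> AlarmEvent:
    """Trigger the alarm for a detected anomaly.

    The alarm fires ``policy.d_beta_default`` ms after detection
    (t_beta = t_alpha + d_beta); the default delay is zero.
    """
    return AlarmEvent(
        alarm_id=alarm_id,
        anomaly=anomaly,
        t_beta=anomaly.t_alpha + policy.d_beta_default,
    )


_REQUIRED_COLUMNS = ["time_ms", "patient_id", "sensor_type", "value"]

Downsample = Literal["first", "mean", "last"]


def read_stream(path, *, downsample: Optional[Downsample] = None) -> list[Reading]:
    """Read a reading stream CSV into a list of Readings.

    Columns ``time_ms,patient_id,sensor_type,value`` (header mandatory,
    UTF-8).  Rows must be non-decreasing in time per patient; missing or
    non-finite values are rejected.  ``downsample`` optionally collapses
    sub-second samples to one reading per (patient, sensor, second) by
    taking the first, mean, or last value of each second.
    """
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except (OSError, ValueError) as exc:
        raise StreamParseError(f"{path}: cannot read CSV: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StreamParseError(f"{path}: missing column(s) {', '.join(missing)}")

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.index[~values.map(math.isfinite)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise StreamParseError(
            f"{path}: line {bad[0] + 2}: missing or non-finite value"
        )
    times = pd.to_numeric(df["time_ms"], errors="coerce")
    bad_time = times.isna() | (times < 0) | (times % 1 != 0)
    if bad_time.any():
        line = int(times.index[bad_time][0])
        raise StreamParseError(f"{path}: line {line + 2}: time_ms must be a non-negative integer")
    df = df.assign(time_ms=times.astype("int64"), value=values.astype(float))
    df["patient_id"] = df["patient_id"].astype(str)
    df["sensor_type"] = df["sensor_type"].astype(str)

    for (pid, sensor), sub in df.groupby(["patient_id", "sensor_type"], sort=False):
        t = sub["time_ms"].to_numpy()
        if (t[1:] < t[:-1]).any():
            i = int(sub.index[1:][t[1:] < t[:-1]][0])
            raise StreamParseError(
                f"{path}: line {i + 2}: time_ms decreases for patient {pid!r}, sensor {sensor!r}"
            )

    if downsample is not None:
        if downsample not in ("first", "mean", "last"):
            raise ValueError(f"unknown downsample rule {downsample!r}")
        df["_sec"] = df["time_ms"] // 1000
        agg = (
            df.groupby(["patient_id", "sensor_type", "_sec"], sort=False)["value"]
            .agg(downsample)
            .reset_index()
        )
        agg["time_ms"] = agg["_sec"] * 1000
        df = agg.sort_values(["time_ms", "patient_id"], kind="stable")

    return [
        Reading(
            patient_id=row.patient_id,
            sensor_type=row.sensor_type,
            value=float(row.value),
            time=int(row.time_ms),
        )
        for row in df.itertuples(index=False)
    ]


def read_routing_key_stream(
    lines_or_path,
    *,
    interval_ms: int = 1000,
    sensor_type: str = "heart_rate",
) -> list[Reading]:
    """Read a routing-key style stream: one ``<patientID>.<value>`` per line.

    This mirrors the message-broker routing-key convention for heart-rate
    streams (e.g. ``16.88`` means patient 16, value 88).  The patient id is
    everything before the first dot.  Readings are timestamped per patient
    at ``interval_ms`` spacing starting from 0.
    """
    if isinstance(lines_or_path, (str, bytes)) or hasattr(lines_or_path, "__fspath__"):
        with open(lines_or_path, "r", encoding="utf-8") as fh:
            lines: Iterable[str] = fh.readlines()
    else:
        lines = list(lines_or_path)
    readings: list[Reading] = []
    counts: dict[str, int] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line:
            continue
        pid, sep, value_text = line.partition(".")
        if not sep or not pid or not value_text:
            raise StreamParseError(f"line {lineno}: expected <patientID>.<value>, got {line!r}")
        try:
            value = float(value_text)
        except ValueError as exc:
            raise StreamParseError(f"line {lineno}: bad value {value_text!r}") from exc
        if not math.isfinite(value):
            raise StreamParseError(f"line {lineno}: non-finite value {value_text!r}")
        i = counts.get(pid, 0)
        counts[pid] = i + 1
        readings.append(
            Reading(patient_id=pid, sensor_type=sensor_type, value=value, time=i * interval_ms)
        )
    readings.sort(key=lambda r: (r.time, r.patient_id))
    return readings
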