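"""Deterministic event-driven replay of monitoring streams.

Replaces a live producer/broker/consumer deployment with an in-process
virtual clock: readings are merged across streams in time order (patient
id breaks ties), anomaly detection and alarm triggering happen at the
reading's stamped time, and scheduled buffer releases fire on the same
clock.  Within one timestamp the order is: readings (and the alarms they
trigger), then alarms whose triggering delay expires now, then buffer
releases — so an alarm triggered exactly at a release instant joins the
outgoing grouped notification rather than waiting a full interval, which
keeps every notification delay strictly below the minimum notification
interval.  Identical inputs produce byte-identical event logs — there is
no wall-clock dependence anywhere.

The module also ships :func:`replay_oracle`, a deliberately naive
reference simulator that walks the clock one millisecond at a time and
applies the notification rule literally.  It exists for testing only (its
cost is proportional to the time horizon, not the number of events) and
must produce an event log identical to :func:`run`.
"""

from __future__ import annotations

import heapq
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

from . import reasoner as _reasoner
from .detection import detect, read_stream, trigger_alarm
from .events import (
    AlarmEvent,
    AnomalyEvent,
    ConfigError,
    ExperimentConfig,
    NotificationEvent,
    Reading,
    validate_config,
)

__all__ = ["EventLog", "run", "replay_oracle", "HorizonExceededError"]

#: refuse per-millisecond oracle runs longer than this (guards slow tests)
ORACLE_MAX_HORIZON_MS = 1_000_000


class HorizonExceededError(ValueError):
    """The per-millisecond oracle was asked to cover too long a horizon."""


# -- event log ---------------------------------------------------------------

def _reading_record(r: Reading) -> dict:
    return {
        "kind": "reading",
        "time": r.time,
        "patient_id": r.patient_id,
        "sensor_type": r.sensor_type,
        "value": r.value,
    }


def _anomaly_record(a: AnomalyEvent) -> dict:
    return {
        "kind": "anomaly",
        "time": a.t_alpha,
        "patient_id": a.patient_id,
        "sensor_type": a.sensor_type,
        "value": a.value,
        "direction": a.direction.value,
    }


def _alarm_record(b: AlarmEvent) -> dict:
    return {
        "kind": "alarm",
        "time": b.t_beta,
        "alarm_id": b.alarm_id,
        "patient_id": b.patient_id,
        "event_type": b.event_type,
        "value": b.anomaly.value,
        "direction": b.anomaly.direction.value,
        "t_alpha": b.anomaly.t_alpha,
        "d_beta": b.d_beta,
    }


def _notification_record(n: NotificationEvent) -> dict:
    return {
        "kind": "notification",
        "time": n.t_mu,
        "notification_id": n.notification_id,
        "patient_id": n.patient_id,
        "event_type": n.event_type,
        "n_alarms": len(n.data),
        "alarm_ids": [a.alarm_id for a in n.data],
        "per_alarm_delay": list(n.per_alarm_delay),
        "first_t_beta": n.data[0].t_beta,
        "last_t_beta": n.data[-1].t_beta,
    }


@dataclass
class EventLog:
    """Append-only, time-ordered record of a replay.

    Each record is a plain dict with a ``kind`` of ``reading``,
    ``anomaly``, ``alarm`` or ``notification`` and the fields of the
    corresponding event; key order is stable so serialized logs are
    byte-reproducible.
    """

    records: list[dict] = field(default_factory=list)

    def __iter__(self) -> Iterator[dict]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return self.records == other.records

    def of_kind(self, kind: str) -> list[dict]:
        return [rec for rec in self.records if rec["kind"] == kind]

    @property
    def readings(self) -> list[dict]:
        return self.of_kind("reading")

    @property
    def anomalies(self) -> list[dict]:
        return self.of_kind("anomaly")

    @property
    def alarms(self) -> list[dict]:
        return self.of_kind("alarm")

    @property
    def notifications(self) -> list[dict]:
        return self.of_kind("notification")

    def write_jsonl(self, path) -> None:
        """Write one JSON object per line, stable key order, integer times."""
        with open(path, "w", encoding="utf-8") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, separators=(",", ":")))
                fh.write("\n")

    @classmethod
    def read_jsonl(cls, path) -> "EventLog":
        records = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
        return cls(records)

    def write_notifications_csv(self, path) -> None:
        """Write the notification timeline as CSV (for delivery plots)."""
        header = "notification_id,patient_id,event_type,t_mu,n_alarms,first_t_beta,last_t_beta"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header + "\n")
            for rec in self.notifications:
                fh.write(
                    f"{rec['notification_id']},{rec['patient_id']},{rec['event_type']},"
                    f"{rec['time']},{rec['n_alarms']},{rec['first_t_beta']},{rec['last_t_beta']}\n"
                )


# -- input handling ----------------------------------------------------------

StreamLike = Union[str, os.PathLike, Sequence[Reading]]


def _collect_readings(streams: Union[StreamLike, Iterable[StreamLike]]) -> list[Reading]:
    if isinstance(streams, (str, os.PathLike)) or (
        streams and isinstance(streams, Sequence) and isinstance(streams[0], Reading)
    ):
        streams = [streams]  # a single stream was passed bare
    readings: list[Reading] = []
    for stream in streams:
        if isinstance(stream, (str, os.PathLike)):
            readings.extend(read_stream(stream))
        else:
            readings.extend(stream)
    # merge by time; patient id breaks ties; stable for same-patient same-time
    readings.sort(key=lambda r: (r.time, r.patient_id))
    return readings


# -- the engine --------------------------------------------------------------

class _Pipeline:
    """Shared detection -> reasoning plumbing for run() and the oracle."""

    def __init__(self, cfg: ExperimentConfig):
        violations = validate_config(cfg)
        if violations:
            raise ConfigError("; ".join(violations))
        self.cfg = cfg
        self.log = EventLog()
        self.states: dict[tuple[str, str], _reasoner.ReasonerState] = {}
        self.next_alarm_id = 1

    def state_for(self, key: tuple[str, str]) -> _reasoner.ReasonerState:
        state = self.states.get(key)
        if state is None:
            state = _reasoner.ReasonerState(patient_id=key[0], event_type=key[1])
            self.states[key] = state
        return state

    def consume_reading(self, reading: Reading) -> Optional[AlarmEvent]:
        """Log the reading; on anomaly, trigger and return the alarm."""
        self.log.records.append(_reading_record(reading))
        anomaly = detect(reading, self.cfg)
        if anomaly is None:
            return None
        self.log.records.append(_anomaly_record(anomaly))
        policy = self.cfg.policy_for(reading.patient_id)
        alarm = trigger_alarm(anomaly, policy, self.next_alarm_id)
        self.next_alarm_id += 1
        return alarm

    def process_alarm(self, alarm: AlarmEvent) -> Optional[int]:
        """Reason about one triggered alarm; return a new release time or None."""
        self.log.records.append(_alarm_record(alarm))
        key = (alarm.patient_id, alarm.event_type)
        state = self.state_for(key)
        policy = self.cfg.policy_for(alarm.patient_id)
        decision = _reasoner.decide(alarm, state, policy)
        if decision.action is _reasoner.Action.NOTIFY_NOW:
            notification = _reasoner.notify_now(alarm, state)
            self.log.records.append(_notification_record(notification))
            return None
        return _reasoner.buffer_alarm(alarm, state, policy)

    def release(self, key: tuple[str, str], now: int) -> None:
        notification = _reasoner.release_buffer(self.states[key], now)
        self.log.records.append(_notification_record(notification))


def run(
    streams: Union[StreamLike, Iterable[StreamLike]],
    cfg: ExperimentConfig,
    *,
    flush_at_end: bool = False,
) -> EventLog:
    """Replay reading streams through detection and reasoning.

    Returns the complete event log.  Scheduled buffer releases after the
    last reading still fire at their scheduled times by default, so every
    alarm ends up in exactly one notification; with ``flush_at_end`` the
    residual buffers are instead emitted at the last reading's time.

    Deterministic: identical inputs yield identical logs.
    """
    pipeline = _Pipeline(cfg)
    readings = _collect_readings(streams)

    # pending scheduled events: (time, kind_rank, seq, payload)
    # kind_rank 0 = delayed alarm, 1 = buffer release: an alarm due at t
    # must be reasoned about before a release fires at t, and readings at
    # t are consumed before either (strict drain below).
    pending: list[tuple[int, int, int, object]] = []
    seq = 0

    def drain_until(t: Optional[int]) -> None:
        # process every scheduled event due strictly before t (all, if t is None)
        while pending and (t is None or pending[0][0] < t):
            when, rank, _, payload = heapq.heappop(pending)
            if rank == 0:
                _handle_alarm(payload)
            else:
                pipeline.release(payload, when)

    def _handle_alarm(alarm: AlarmEvent) -> None:
        nonlocal seq
        release_time = pipeline.process_alarm(alarm)
        if release_time is not None:
            key = (alarm.patient_id, alarm.event_type)
            heapq.heappush(pending, (release_time, 1, seq, key))
            seq += 1

    last_time = 0
    for reading in readings:
        drain_until(reading.time)
        last_time = max(last_time, reading.time)
        alarm = pipeline.consume_reading(reading)
        if alarm is None:
            continue
        if alarm.t_beta == reading.time:
            _handle_alarm(alarm)
        else:
            heapq.heappush(pending, (alarm.t_beta, 0, seq, alarm))
            seq += 1

    if flush_at_end:
        # deliver delayed alarms first, then emit residual buffers at the
        # last reading's time instead of waiting out the schedule
        while pending:
            when, rank, _, payload = heapq.heappop(pending)
            if rank == 0:
                _handle_alarm(payload)
        open_keys = sorted(k for k, s in pipeline.states.items() if s.buffer is not None)
        for key in open_keys:
            buf = pipeline.states[key].buffer
            pipeline.release(key, max(last_time, buf.alarms[-1].t_beta))
    else:
        drain_until(None)
    return pipeline.log


# -- per-millisecond reference simulator -------------------------------------

def replay_oracle(
    streams: Union[StreamLike, Iterable[StreamLike]],
    cfg: ExperimentConfig,
    *,
    flush_at_end: bool = False,
    max_horizon_ms: int = ORACLE_MAX_HORIZON_MS,
) -> EventLog:
    """Naive reference replay: advance the clock one millisecond at a time.

    At every tick it first evaluates the readings stamped at this tick,
    then triggers any alarm whose delay expires now, then releases any
    buffer whose scheduled time has arrived — re-deriving each decision
    directly from the rate-limiting rule.  Intended as a test oracle on
    small inputs; refuses horizons beyond ``max_horizon_ms``.
    """
    pipeline = _Pipeline(cfg)
    readings = _collect_readings(streams)

    by_time: dict[int, list[Reading]] = {}
    for r in readings:
        by_time.setdefault(r.time, []).append(r)

    delayed_alarms: dict[int, list[AlarmEvent]] = {}
    release_schedule: dict[int, list[tuple[str, str]]] = {}

    last_reading_time = max((r.time for r in readings), default=-1)
    horizon = last_reading_time
    if not flush_at_end:
        max_d_beta = max(
            (cfg.policy_for(r.patient_id).d_beta_default for r in readings), default=0
        )
        max_mni = max(
            [cfg.policy.mni] + [p.mni for p in cfg.policy_overrides.values()]
        )
        horizon = last_reading_time + max_d_beta + max_mni
    if horizon > max_horizon_ms:
        raise HorizonExceededError(
            f"oracle horizon {horizon} ms exceeds the {max_horizon_ms} ms guard"
        )

    def handle_alarm(alarm: AlarmEvent) -> None:
        release_time = pipeline.process_alarm(alarm)
        if release_time is not None:
            key = (alarm.patient_id, alarm.event_type)
            release_schedule.setdefault(release_time, []).append(key)

    now = 0
    while now <= horizon:
        for reading in by_time.get(now, ()):
            alarm = pipeline.consume_reading(reading)
            if alarm is None:
                continue
            if alarm.t_beta == now:
                handle_alarm(alarm)
            else:
                delayed_alarms.setdefault(alarm.t_beta, []).append(alarm)
        for alarm in delayed_alarms.pop(now, ()):
            handle_alarm(alarm)
        for key in release_schedule.pop(now, ()):
            state = pipeline.states[key]
            if state.buffer is not None and state.buffer.release_time == now:
                pipeline.release(key, now)
        if not flush_at_end and not release_schedule and not delayed_alarms and now >= last_reading_time:
            break  # nothing left on the schedule; clock has nothing to wait for
        now += 1

    if flush_at_end:
        for t in sorted(delayed_alarms):
            for alarm in delayed_alarms[t]:
                handle_alarm(alarm)
        open_keys = sorted(k for k, s in pipeline.states.items() if s.buffer is not None)
        for key in open_keys:
            buf = pipeline.states[key].buffer
            pipeline.release(key, max(last_reading_time, 0, buf.alarms[-1].t_beta))
    return pipeline.log
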