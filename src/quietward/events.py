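"""Domain types for the alarm-fatigue notification pipeline.

The pipeline distinguishes three events in the life of an anomalous vital
sign: the *anomaly-detected* event (alpha) raised when a reading leaves its
configured normal range, the *alarm-triggering* event (beta) that indicates
the anomaly to the system, and the *notification* event (mu) that actually
reaches the caregivers.  Two delays connect them:

    d_beta = t_beta - t_alpha   (detection -> alarm)
    d_mu   = t_mu   - t_beta    (alarm -> notification, one per alarm)

All times are integer milliseconds from a stream-local epoch, which keeps
every delay an exact integer subtraction.

A per-(patient, alarm-type) *minimum notification interval* (MNI) governs
delivery: two notifications of the same type for the same patient must be
at least MNI apart.  Alarms arriving inside that window are buffered and
delivered together as one grouped notification.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import yaml

__all__ = [
    "Direction",
    "Reading",
    "ThresholdConfig",
    "AnomalyEvent",
    "AlarmEvent",
    "NotificationEvent",
    "AnomalyState",
    "NotificationPolicy",
    "ExperimentConfig",
    "next_state",
    "validate_config",
    "load_config",
    "dump_config",
    "ConfigError",
    "StreamParseError",
    "InvalidTransitionError",
    "CausalityError",
]


class ConfigError(ValueError):
    """Missing or inconsistent experiment configuration."""


class StreamParseError(ValueError):
    """Malformed reading stream (bad value, bad ordering, bad columns)."""


class InvalidTransitionError(ValueError):
    """Illegal transition requested on the anomaly state machine."""


class CausalityError(ValueError):
    """An event time precedes the event it must follow."""


class Direction(str, enum.Enum):
    """Which side of the normal range a reading violated."""

    LOW = "low"
    HIGH = "high"
    NONE = "none"


@dataclass(frozen=True)
class Reading:
    """One timestamped sensor value for one patient.

    ``time`` is in integer milliseconds from the stream epoch; ``value`` is
    in the sensor's clinical units (beats/min for heart rate).
    """

    patient_id: str
    sensor_type: str
    value: float
    time: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"reading time must be >= 0, got {self.time}")
        if not math.isfinite(self.value):
            raise ValueError(f"reading value must be finite, got {self.value}")
        if not self.sensor_type:
            raise ValueError("sensor_type must be non-empty")


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-(sensor, patient) normal range [v_min, v_max].

    A reading is anomalous iff strictly below ``v_min`` or strictly above
    ``v_max``; values equal to a limit are normal.  The ``v_min < v_max``
    invariant is checked by :func:`validate_config`, not at construction,
    so that a bad config can be reported rather than raised.
    """

    patient_id: str
    sensor_type: str
    v_min: float
    v_max: float

    @property
    def key(self) -> tuple[str, str]:
        return (self.patient_id, self.sensor_type)


@dataclass(frozen=True)
class AnomalyEvent:
    """Anomaly-detected event (alpha): a reading outside its thresholds."""

    patient_id: str
    sensor_type: str
    value: float
    t_alpha: int
    direction: Direction

    event_type = "anomaly_detected"

    def __post_init__(self) -> None:
        if self.direction is Direction.NONE:
            raise ValueError("an anomaly must have a low/high direction")
        if self.t_alpha < 0:
            raise ValueError("t_alpha must be >= 0")


@dataclass(frozen=True)
class AlarmEvent:
    """Alarm-triggering event (beta) wrapping the anomaly it indicates.

    The alarm type used for grouping is the sensor parameter only
    (``heart_rate``), not the direction: same-type alarms for one patient
    share one notification stream regardless of low/high.  Direction
    remains available on the wrapped anomaly.
    """

    alarm_id: int
    anomaly: AnomalyEvent
    t_beta: int

    def __post_init__(self) -> None:
        if self.t_beta < self.anomaly.t_alpha:
            raise CausalityError(
                f"t_beta={self.t_beta} precedes t_alpha={self.anomaly.t_alpha}"
            )

    @property
    def patient_id(self) -> str:
        return self.anomaly.patient_id

    @property
    def event_type(self) -> str:
        return self.anomaly.sensor_type

    @property
    def d_beta(self) -> int:
        """Alarm-triggering delay, t_beta - t_alpha."""
        return self.t_beta - self.anomaly.t_alpha


@dataclass(frozen=True)
class NotificationEvent:
    """Notification event (mu) delivering one alarm or a grouped set.

    ``data`` is ordered by alarm trigger time; all alarms share the
    notification's patient and type.  ``per_alarm_delay[i]`` is the
    notification delay d_mu of ``data[i]``.
    """

    notification_id: int
    patient_id: str
    event_type: str
    t_mu: int
    data: tuple[AlarmEvent, ...]

    def __post_init__(self) -> None:
        if not self.data:
            raise ValueError("a notification must carry at least one alarm")
        for alarm in self.data:
            if alarm.patient_id != self.patient_id or alarm.event_type != self.event_type:
                raise ValueError("all alarms in a notification must share patient and type")
            if alarm.t_beta > self.t_mu:
                raise CausalityError(
                    f"t_mu={self.t_mu} precedes alarm t_beta={alarm.t_beta}"
                )

    @property
    def per_alarm_delay(self) -> tuple[int, ...]:
        return tuple(self.t_mu - alarm.t_beta for alarm in self.data)


class AnomalyState(enum.Enum):
    """Lifecycle states of a single anomaly instance."""

    NO_ANOMALY = "no_anomaly"
    ANOMALY_ALERTED = "anomaly_alerted"
    ANOMALY_ALERTED_UNDER_REASONING = "anomaly_alerted_under_reasoning"
    ANOMALY_NOTIFIED = "anomaly_notified"


#: Legal (state, event) -> state transitions.  An alerted anomaly may be
#: notified directly (immediate delivery) or pass through the buffered
#: "under reasoning" state first; NOTIFIED is terminal.
_TRANSITIONS: dict[tuple[AnomalyState, str], AnomalyState] = {
    (AnomalyState.NO_ANOMALY, "anomaly_detected"): AnomalyState.ANOMALY_ALERTED,
    (AnomalyState.ANOMALY_ALERTED, "alarm_buffered"): AnomalyState.ANOMALY_ALERTED_UNDER_REASONING,
    (AnomalyState.ANOMALY_ALERTED, "alarm_notified"): AnomalyState.ANOMALY_NOTIFIED,
    (AnomalyState.ANOMALY_ALERTED_UNDER_REASONING, "alarm_notified"): AnomalyState.ANOMALY_NOTIFIED,
}

TRANSITION_EVENTS = ("anomaly_detected", "alarm_buffered", "alarm_notified")


def next_state(current: AnomalyState, event: str) -> AnomalyState:
    """Advance the anomaly state machine by one transition.

    Raises :class:`InvalidTransitionError` for any (state, event) pair not
    on the machine; in particular NOTIFIED is terminal and no state may be
    revisited for one anomaly instance.
    """
    if event not in TRANSITION_EVENTS:
        raise InvalidTransitionError(f"unknown transition event {event!r}")
    try:
        return _TRANSITIONS[(current, event)]
    except KeyError:
        raise InvalidTransitionError(
            f"no transition from {current.name} on {event!r}"
        ) from None


@dataclass(frozen=True)
class NotificationPolicy:
    """Notification timing policy.

    mni
        Minimum notification interval in ms: the smallest allowed gap
        between two delivered notifications of the same type for the same
        patient.  The reference configuration uses 5 min (300,000 ms).
    d_beta_default
        Alarm-triggering delay applied between anomaly detection and the
        alarm event; 0 by default (alarm fires at detection time).
    """

    mni: int
    d_beta_default: int = 0


@dataclass
class ExperimentConfig:
    """Experiment scaffold: monitored population, sampling, thresholds, policy.

    ``policy`` is the default for every patient; ``policy_overrides`` maps
    individual patient ids to their own policy where they differ.
    """

    number_of_wards: int
    number_of_patients: int
    number_of_sensors: int
    sensors_reading_interval: int
    number_of_readings: int
    thresholds: dict[tuple[str, str], ThresholdConfig]
    policy: NotificationPolicy
    policy_overrides: dict[str, NotificationPolicy] = field(default_factory=dict)

    def threshold_for(self, patient_id: str, sensor_type: str) -> ThresholdConfig:
        try:
            return self.thresholds[(patient_id, sensor_type)]
        except KeyError:
            raise ConfigError(
                f"no threshold configured for patient {patient_id!r}, sensor {sensor_type!r}"
            ) from None

    def policy_for(self, patient_id: str) -> NotificationPolicy:
        return self.policy_overrides.get(patient_id, self.policy)


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Return a list of human-readable config violations (empty iff valid).

    Checks every threshold satisfies v_min < v_max, every policy has a
    positive MNI and non-negative alarm delay, and the experiment counts
    are positive.  Violations are returned, never raised.
    """
    violations: list[str] = []
    for name in (
        "number_of_wards",
        "number_of_patients",
        "number_of_sensors",
        "sensors_reading_interval",
        "number_of_readings",
    ):
        if getattr(cfg, name) <= 0:
            violations.append(f"{name} must be positive, got {getattr(cfg, name)}")
    for key, thr in cfg.thresholds.items():
        if key != thr.key:
            violations.append(f"threshold keyed {key} has fields {thr.key}")
        if not (thr.v_min < thr.v_max):
            violations.append(
                f"threshold for patient {thr.patient_id!r}, sensor {thr.sensor_type!r}: "
                f"v_min={thr.v_min} must be < v_max={thr.v_max}"
            )
    policies = [("default", cfg.policy)] + [
        (f"patient {pid!r}", pol) for pid, pol in sorted(cfg.policy_overrides.items())
    ]
    for label, pol in policies:
        if pol.mni <= 0:
            violations.append(f"{label} policy: mni must be > 0, got {pol.mni}")
        if pol.d_beta_default < 0:
            violations.append(
                f"{label} policy: d_beta_default must be >= 0, got {pol.d_beta_default}"
            )
    return violations


# -- config file I/O ---------------------------------------------------------

def _policy_from_mapping(raw: dict) -> NotificationPolicy:
    return NotificationPolicy(
        mni=int(raw["mni_ms"]),
        d_beta_default=int(raw.get("d_beta_ms", 0)),
    )


def load_config(path) -> ExperimentConfig:
    """Load an experiment configuration from YAML.

    Expected sections: ``experiment`` (counts and sampling interval),
    ``thresholds`` (list of {patient_id, sensor_type, min, max}),
    ``policy`` ({mni_ms, d_beta_ms}) with optional per-patient overrides
    under ``policy.overrides`` keyed by patient id.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a mapping")
    try:
        exp = raw["experiment"]
        thresholds = {}
        for row in raw["thresholds"]:
            thr = ThresholdConfig(
                patient_id=str(row["patient_id"]),
                sensor_type=str(row["sensor_type"]),
                v_min=float(row["min"]),
                v_max=float(row["max"]),
            )
            if thr.key in thresholds:
                raise ConfigError(f"duplicate threshold for {thr.key}")
            thresholds[thr.key] = thr
        policy_raw = dict(raw["policy"])
        overrides_raw = policy_raw.pop("overrides", {}) or {}
        cfg = ExperimentConfig(
            number_of_wards=int(exp["number_of_wards"]),
            number_of_patients=int(exp["number_of_patients"]),
            number_of_sensors=int(exp["number_of_sensors"]),
            sensors_reading_interval=int(exp["sensors_reading_interval_ms"]),
            number_of_readings=int(exp["number_of_readings"]),
            thresholds=thresholds,
            policy=_policy_from_mapping(policy_raw),
            policy_overrides={
                str(pid): _policy_from_mapping(sub) for pid, sub in overrides_raw.items()
            },
        )
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(f"malformed config file {path}: {exc}") from exc
    return cfg


def dump_config(cfg: ExperimentConfig, path) -> None:
    """Write an experiment configuration as YAML (inverse of load_config)."""
    raw = {
        "experiment": {
            "number_of_wards": cfg.number_of_wards,
            "number_of_patients": cfg.number_of_patients,
            "number_of_sensors": cfg.number_of_sensors,
            "sensors_reading_interval_ms": cfg.sensors_reading_interval,
            "number_of_readings": cfg.number_of_readings,
        },
        "thresholds": [
            {
                "patient_id": thr.patient_id,
                "sensor_type": thr.sensor_type,
                "min": thr.v_min,
                "max": thr.v_max,
            }
            for thr in cfg.thresholds.values()
        ],
        "policy": {
            "mni_ms": cfg.policy.mni,
            "d_beta_ms": cfg.policy.d_beta_default,
            **(
                {
                    "overrides": {
                        pid: {"mni_ms": pol.mni, "d_beta_ms": pol.d_beta_default}
                        for pid, pol in cfg.policy_overrides.items()
                    }
                }
                if cfg.policy_overrides
                else {}
            ),
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)
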