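"""Notification reasoning: rate-limit and group same-type, same-patient alarms.

The reasoner enforces one rule: caregivers receive at most one notification
of a given alarm type for a given patient per minimum notification interval
(MNI).  For each triggered alarm it computes the *last notification period*

    LNP = t_beta_r - t_mu_k

(the time since the last same-type notification for the patient) and
decides:

* no prior notification, or LNP >= MNI, and no buffer open  ->  deliver
  immediately (t_mu = t_beta, zero notification delay);
* otherwise  ->  queue the alarm into the per-(patient, type) buffer.

The first buffered alarm opens the buffer and fixes its release time at
``t_mu_k + MNI`` — exactly one MNI after the previous delivery — so that
consecutive notifications are always >= MNI apart and every buffered alarm
waits strictly less than MNI.  At release the whole buffer is wrapped into
a single grouped notification; an alarm triggered exactly at the release
instant joins the outgoing notification, keeping every buffering period
strictly below MNI.

State is mutated in place; one :class:`ReasonerState` exists per
(patient_id, event_type) key and keys never share buffers.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from .events import AlarmEvent, CausalityError, NotificationEvent, NotificationPolicy

__all__ = [
    "Action",
    "Decision",
    "AlarmBuffer",
    "ReasonerState",
    "compute_lnp",
    "decide",
    "buffer_alarm",
    "release_buffer",
    "notify_now",
]


class Action(enum.Enum):
    NOTIFY_NOW = "notify_now"
    BUFFER = "buffer"


@dataclass(frozen=True)
class Decision:
    """Outcome of the per-alarm reasoning step."""

    action: Action
    lnp: int  # last notification period at decision time, ms

    def __post_init__(self) -> None:
        if self.lnp < 0:
            raise ValueError("LNP must be >= 0")


@dataclass
class AlarmBuffer:
    """Holding area for alarms awaiting grouped delivery.

    ``starting_time`` is the trigger time of the first queued alarm;
    ``release_time`` is fixed at creation and never moves when later
    alarms append.
    """

    starting_time: int
    release_time: int
    alarms: list[AlarmEvent]

    def __post_init__(self) -> None:
        if not self.alarms:
            raise ValueError("a buffer is created with its first alarm")
        if self.release_time <= self.starting_time:
            raise ValueError("release_time must follow starting_time")


@dataclass
class ReasonerState:
    """Per-(patient, alarm-type) reasoning state.

    ``t_mu_k`` is the last notification time; it is absent (None) until
    the first delivery for this key — absence, not a zero sentinel, marks
    "never notified".  At most one buffer is open per key.
    """

    patient_id: str
    event_type: str
    t_mu_k: Optional[int] = None
    buffer: Optional[AlarmBuffer] = None
    next_notification_id: int = 1


def compute_lnp(t_beta_r: int, t_mu_k: Optional[int]) -> int:
    """Last notification period: t_beta_r - t_mu_k.

    When no notification has ever been delivered for this key
    (``t_mu_k is None``) the period equals ``t_beta_r`` itself — the
    elapsed time since the stream epoch.
    """
    if t_mu_k is None:
        return t_beta_r
    if t_mu_k > t_beta_r:
        raise CausalityError(
            f"last notification at {t_mu_k} is after the current alarm at {t_beta_r}"
        )
    return t_beta_r - t_mu_k


def _check_key(alarm: AlarmEvent, state: ReasonerState) -> None:
    if (alarm.patient_id, alarm.event_type) != (state.patient_id, state.event_type):
        raise ValueError(
            f"alarm for ({alarm.patient_id!r}, {alarm.event_type!r}) routed to reasoner "
            f"state ({state.patient_id!r}, {state.event_type!r})"
        )


def decide(alarm: AlarmEvent, state: ReasonerState, policy: NotificationPolicy) -> Decision:
    """Decide whether to deliver ``alarm`` immediately or buffer it.

    Immediate delivery requires that no buffer is open and either no
    notification was ever sent for this key or the last one is at least
    MNI old (LNP >= MNI, boundary inclusive).  While a buffer is open
    every alarm joins it.
    """
    _check_key(alarm, state)
    lnp = compute_lnp(alarm.t_beta, state.t_mu_k)
    if state.buffer is not None:
        return Decision(Action.BUFFER, lnp)
    if state.t_mu_k is None or lnp >= policy.mni:
        return Decision(Action.NOTIFY_NOW, lnp)
    return Decision(Action.BUFFER, lnp)


def buffer_alarm(
    alarm: AlarmEvent, state: ReasonerState, policy: NotificationPolicy
) -> Optional[int]:
    """Queue ``alarm`` for grouped delivery.

    If this alarm opens the buffer, the release is scheduled one MNI after
    the last notification and its time is returned so the caller can
    schedule the release event; appending to an open buffer returns None
    and never moves the release time.
    """
    _check_key(alarm, state)
    if state.buffer is None:
        if state.t_mu_k is None:
            raise RuntimeError("cannot buffer before any notification exists for this key")
        release_time = state.t_mu_k + policy.mni
        if release_time <= alarm.t_beta:
            # decide() only buffers when lnp < mni, which makes release > t_beta
            raise RuntimeError(
                f"scheduling contradiction: release at {release_time} "
                f"not after alarm at {alarm.t_beta}"
            )
        state.buffer = AlarmBuffer(
            starting_time=alarm.t_beta,
            release_time=release_time,
            alarms=[alarm],
        )
        return release_time
    buf = state.buffer
    # maintain t_beta order; same-time alarms keep arrival order
    i = len(buf.alarms)
    while i > 0 and buf.alarms[i - 1].t_beta > alarm.t_beta:
        i -= 1
    buf.alarms.insert(i, alarm)
    return None


def release_buffer(state: ReasonerState, now: int) -> NotificationEvent:
    """Release the open buffer as one grouped notification at time ``now``.

    Normally ``now`` equals the buffer's scheduled release time; an early
    release (end-of-stream flush) is permitted as long as every queued
    alarm has already triggered.  Clears the buffer and records ``now`` as
    the last notification time.
    """
    if state.buffer is None:
        raise RuntimeError(
            f"no open buffer for ({state.patient_id!r}, {state.event_type!r})"
        )
    buf = state.buffer
    notification = NotificationEvent(
        notification_id=state.next_notification_id,
        patient_id=state.patient_id,
        event_type=state.event_type,
        t_mu=now,
        data=tuple(buf.alarms),
    )
    state.buffer = None
    state.t_mu_k = now
    state.next_notification_id += 1
    return notification


def notify_now(alarm: AlarmEvent, state: ReasonerState) -> NotificationEvent:
    """Deliver ``alarm`` immediately as a single-alarm notification.

    The notification fires at the alarm's own trigger time, so its
    notification delay is exactly zero.
    """
    _check_key(alarm, state)
    notification = NotificationEvent(
        notification_id=state.next_notification_id,
        patient_id=state.patient_id,
        event_type=state.event_type,
        t_mu=alarm.t_beta,
        data=(alarm,),
    )
    state.t_mu_k = alarm.t_beta
    state.next_notification_id += 1
    return notification
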