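"""Evaluation metrics and invariant audits for replay event logs.

Percentages are *floor-truncated*, not rounded: the notification share is
trunc1(100 * n_notifications / n_alarms) and the reduction is
trunc1(100 * (n_alarms - n_notifications) / n_alarms), both to one
decimal; the pooled mean reduction across experiments is truncated to two
decimals.  Truncation is pinned by the reference result tables (586
alarms collapsing to 4 notifications reads 0.6%, which 0.6826 truncates
to but rounds away from).  All truncation is exact integer arithmetic —
no floating-point division is involved until the final display value.

The pooled mean aggregates alarms and notifications before dividing
(sum over experiments), not an average of per-experiment percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .events import NotificationPolicy
from .engine import EventLog

__all__ = [
    "ExperimentSummary",
    "AuditReport",
    "summarize",
    "summarize_counts",
    "mean_reduction",
    "audit",
    "truncate_pct",
]


def truncate_pct(numerator: int, denominator: int, decimals: int) -> float:
    """Floor-truncate 100*numerator/denominator to ``decimals`` places.

    Computed in integer arithmetic: trunc(0.6826..., 1) == 0.6 even
    though it would round to 0.7.
    """
    if denominator <= 0:
        raise ZeroDivisionError("denominator must be positive")
    scale = 10 ** decimals
    return (100 * numerator * scale // denominator) / scale


@dataclass(frozen=True)
class ExperimentSummary:
    """Alarm/notification counts and truncated percentages for one log.

    ``pct_notified`` and ``pct_reduction`` are None when the log contains
    no alarms (the ratios are undefined, not zero).  ``mni_violations``
    is None when no policy was supplied to audit spacing against.
    """

    experiment_id: Optional[int]
    n_alarms: int
    n_notifications: int
    pct_notified: Optional[float]
    pct_reduction: Optional[float]
    max_delay_ms: int
    mni_violations: Optional[int]

    def __post_init__(self) -> None:
        if self.n_notifications > self.n_alarms:
            raise ValueError("cannot deliver more notifications than alarms")


def summarize_counts(
    n_alarms: int, n_notifications: int, *, experiment_id: Optional[int] = None
) -> ExperimentSummary:
    """Summary from bare (alarms, notifications) counts — no log needed."""
    if n_alarms == 0:
        pct_notified = pct_reduction = None
    else:
        pct_notified = truncate_pct(n_notifications, n_alarms, 1)
        pct_reduction = truncate_pct(n_alarms - n_notifications, n_alarms, 1)
    return ExperimentSummary(
        experiment_id=experiment_id,
        n_alarms=n_alarms,
        n_notifications=n_notifications,
        pct_notified=pct_notified,
        pct_reduction=pct_reduction,
        max_delay_ms=0,
        mni_violations=None,
    )


def summarize(
    log: EventLog,
    *,
    experiment_id: Optional[int] = None,
    policy: Optional[NotificationPolicy] = None,
) -> ExperimentSummary:
    """Summarize a replay log: counts, truncated percentages, delay maximum.

    With a ``policy`` the minimum-notification-interval spacing is audited
    and the violation count included; otherwise it is None.
    """
    n_alarms = len(log.alarms)
    n_notifications = len(log.notifications)
    base = summarize_counts(n_alarms, n_notifications, experiment_id=experiment_id)
    max_delay = max(
        (d for rec in log.notifications for d in rec["per_alarm_delay"]), default=0
    )
    violations: Optional[int] = None
    if policy is not None:
        violations = audit(log, policy).spacing_violations
    return ExperimentSummary(
        experiment_id=experiment_id,
        n_alarms=n_alarms,
        n_notifications=n_notifications,
        pct_notified=base.pct_notified,
        pct_reduction=base.pct_reduction,
        max_delay_ms=max_delay,
        mni_violations=violations,
    )


def mean_reduction(summaries: Sequence[ExperimentSummary]) -> float:
    """Pooled percent reduction across experiments, truncated to 2 decimals.

    Pools alarms and notifications first (sum/sum), then truncates —
    1912 suppressed out of 1928 gives 99.17, not the average of the
    per-experiment percentages.
    """
    if not summaries:
        raise ValueError("mean_reduction needs at least one summary")
    total_alarms = sum(s.n_alarms for s in summaries)
    total_notifications = sum(s.n_notifications for s in summaries)
    if total_alarms == 0:
        raise ValueError("no alarms across the pooled summaries")
    return truncate_pct(total_alarms - total_notifications, total_alarms, 2)


@dataclass(frozen=True)
class AuditReport:
    """Invariant audit of an event log against the notification policy.

    spacing_violations
        consecutive same-(patient, type) notifications closer than MNI;
    missing_alarms
        alarms that appear in no notification;
    duplicated_alarms
        alarms that appear in more than one notification (or twice in one);
    delay_violations
        per-alarm notification delays outside [0, MNI).
    All four are zero for any log the replay engine produces with
    end-of-stream draining enabled.
    """

    spacing_violations: int
    missing_alarms: int
    duplicated_alarms: int
    delay_violations: int

    @property
    def ok(self) -> bool:
        return (
            self.spacing_violations == 0
            and self.missing_alarms == 0
            and self.duplicated_alarms == 0
            and self.delay_violations == 0
        )


def audit(log: EventLog, policy: NotificationPolicy) -> AuditReport:
    """Audit spacing, conservation and delay bounds; pure function of the log."""
    notifications = log.notifications

    spacing = 0
    last_t_mu: dict[tuple[str, str], int] = {}
    for rec in notifications:
        key = (rec["patient_id"], rec["event_type"])
        prev = last_t_mu.get(key)
        if prev is not None and rec["time"] - prev < policy.mni:
            spacing += 1
        last_t_mu[key] = rec["time"]

    seen: dict[int, int] = {}
    for rec in notifications:
        for alarm_id in rec["alarm_ids"]:
            seen[alarm_id] = seen.get(alarm_id, 0) + 1
    all_alarm_ids = [rec["alarm_id"] for rec in log.alarms]
    missing = sum(1 for aid in all_alarm_ids if aid not in seen)
    duplicated = sum(1 for count in seen.values() if count > 1)

    delay_violations = sum(
        1
        for rec in notifications
        for d in rec["per_alarm_delay"]
        if not (0 <= d < policy.mni)
    )
    return AuditReport(
        spacing_violations=spacing,
        missing_alarms=missing,
        duplicated_alarms=duplicated,
        delay_violations=delay_violations,
    )
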