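"""Replay engine: determinism, ordering, oracle agreement, log output."""

import pytest

from quietward.engine import EventLog, HorizonExceededError, replay_oracle, run
from quietward.events import (
    ConfigError,
    ExperimentConfig,
    NotificationPolicy,
    Reading,
    ThresholdConfig,
)

MNI = 300_000


def hr_readings(values, interval=1000, patient="1"):
    return [
        Reading(patient, "heart_rate", float(v), i * interval)
        for i, v in enumerate(values)
    ]


def small_cfg(mni=MNI, d_beta=0, thresholds=None, interval=1000, n=100):
    thresholds = thresholds or [ThresholdConfig("1", "heart_rate", 60.0, 100.0)]
    return ExperimentConfig(
        number_of_wards=1,
        number_of_patients=len({t.patient_id for t in thresholds}),
        number_of_sensors=1,
        sensors_reading_interval=interval,
        number_of_readings=n,
        thresholds={t.key: t for t in thresholds},
        policy=NotificationPolicy(mni=mni, d_beta_default=d_beta),
    )


class TestRunBasics:
    def test_in_range_stream_produces_no_events(self):
        log = run(hr_readings([80] * 50), small_cfg())
        assert len(log.readings) == 50
        assert log.anomalies == [] and log.alarms == [] and log.notifications == []

    def test_single_anomaly_full_chain_at_one_instant(self):
        log = run(hr_readings([80, 120, 80]), small_cfg())
        assert len(log.anomalies) == len(log.alarms) == len(log.notifications) == 1
        a, b, n = log.anomalies[0], log.alarms[0], log.notifications[0]
        assert a["time"] == b["time"] == n["time"] == 1000
        assert b["d_beta"] == 0 and n["per_alarm_delay"] == [0]

    def test_one_alarm_per_anomalous_reading_no_merging(self):
        values = [80, 120, 121, 122, 80, 40, 41, 80]
        log = run(hr_readings(values), small_cfg())
        assert len(log.alarms) == 5  # three high + two low, each its own alarm

    def test_invalid_config_aborts_before_processing(self):
        cfg = small_cfg(mni=0)
        with pytest.raises(ConfigError):
            run(hr_readings([80]), cfg)

    def test_contiguous_run_groups_into_immediate_plus_releases(self):
        # 10 anomalous seconds, MNI = 4 s: immediate at t=0, then grouped
        # releases every 4 s; alarms at exactly t=4 s and t=8 s ride their
        # releases, and the t=9 s straggler waits for the next window.
        log = run(hr_readings([120] * 10), small_cfg(mni=4000))
        notif = log.notifications
        assert [n["time"] for n in notif] == [0, 4000, 8000, 12000]
        assert [n["n_alarms"] for n in notif] == [1, 4, 4, 1]
        assert max(d for n in notif for d in n["per_alarm_delay"]) < 4000

    def test_releases_fire_after_the_last_reading_by_default(self):
        # anomalies at the stream tail: buffer still releases at its schedule
        log = run(hr_readings([80] * 5 + [120, 120]), small_cfg())
        assert [n["time"] for n in log.notifications] == [5000, 5000 + MNI]

    def test_flush_at_end_emits_residual_buffer_at_last_reading(self):
        log = run(hr_readings([80] * 5 + [120, 120]), small_cfg(), flush_at_end=True)
        assert [n["time"] for n in log.notifications] == [5000, 6000]

    def test_deterministic_byte_identical_output(self, tmp_path):
        readings = hr_readings([80, 120, 121, 40, 80, 122] * 20)
        paths = []
        for name in ("a.jsonl", "b.jsonl"):
            log = run(readings, small_cfg())
            path = tmp_path / name
            log.write_jsonl(path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_alarm_triggering_delay_shifts_the_whole_chain(self):
        log = run(hr_readings([120, 80, 80]), small_cfg(d_beta=250))
        assert log.anomalies[0]["time"] == 0
        assert log.alarms[0]["time"] == 250
        assert log.notifications[0]["time"] == 250
        assert log.alarms[0]["d_beta"] == 250


class TestMultiPatient:
    def test_streams_merge_by_time_then_patient_and_never_cross_contaminate(self):
        thr = [
            ThresholdConfig("1", "heart_rate", 60.0, 100.0),
            ThresholdConfig("2", "heart_rate", 60.0, 100.0),
        ]
        cfg = small_cfg(thresholds=thr)
        s1 = hr_readings([120] * 10, patient="1")
        s2 = hr_readings([120] * 10, patient="2")
        log = run([s1, s2], cfg)
        # each patient gets its own immediate notification and its own buffer
        assert len(log.notifications) == 4
        by_patient = {}
        for n in log.notifications:
            by_patient.setdefault(n["patient_id"], []).append(n)
        for pid in ("1", "2"):
            assert [n["time"] for n in by_patient[pid]] == [0, MNI]
        # merged reading order: time ascending, patient id breaking ties
        heads = [(r["time"], r["patient_id"]) for r in log.readings[:4]]
        assert heads == [(0, "1"), (0, "2"), (1000, "1"), (1000, "2")]


class TestOracle:
    def test_empty_stream_gives_empty_log(self):
        assert replay_oracle([], small_cfg()) == EventLog([])

    def test_hand_checkable_ten_alarm_run(self):
        # ten per-second alarms, MNI 4 s: 1 immediate + 3 grouped releases
        log = replay_oracle(hr_readings([120] * 10), small_cfg(mni=4000))
        assert [n["n_alarms"] for n in log.notifications] == [1, 4, 4, 1]

    def test_horizon_guard_refuses_slow_runs(self):
        readings = hr_readings([80], interval=1000)
        cfg = small_cfg(mni=2_000_000)
        with pytest.raises(HorizonExceededError):
            replay_oracle(hr_readings([120]), cfg)
        assert run(readings, cfg)  # the engine itself has no such limit

    def test_engine_matches_oracle_event_for_event(self, oracle_suite):
        for cfg, readings, engine_log, oracle_log in oracle_suite:
            assert engine_log == oracle_log

    def test_engine_matches_oracle_with_triggering_delay_and_flush(self):
        readings = hr_readings([120, 80, 121, 122, 80] * 4, interval=100)
        for flush in (False, True):
            cfg = small_cfg(mni=700, d_beta=30, interval=100)
            assert run(readings, cfg, flush_at_end=flush) == replay_oracle(
                readings, cfg, flush_at_end=flush
            )


class TestClosedForm:
    @pytest.mark.parametrize("n_alarms", [1, 2, 7, 150, 300, 301, 302, 500, 601, 602])
    def test_contiguous_run_notification_count(self, n_alarms):
        """A maximal run of n per-second alarms from an idle key yields
        1 + ceil((n-1)*1000/MNI) notifications (1 for n == 1)."""
        mni = 300_000
        log = run(hr_readings([120] * n_alarms), small_cfg(mni=mni, n=n_alarms))
        expected = 1 if n_alarms == 1 else 1 + -((-(n_alarms - 1) * 1000) // mni)
        assert len(log.notifications) == expected
        # conservation within the run
        assert sum(n["n_alarms"] for n in log.notifications) == n_alarms


class TestLogOutput:
    def test_jsonl_round_trip(self, tmp_path):
        log = run(hr_readings([80, 120, 80]), small_cfg())
        path = tmp_path / "log.jsonl"
        log.write_jsonl(path)
        assert EventLog.read_jsonl(path) == log

    def test_notifications_csv_shape(self, tmp_path):
        log = run(hr_readings([120] * 10), small_cfg(mni=4000))
        path = tmp_path / "notifications.csv"
        log.write_notifications_csv(path)
        lines = path.read_text(encoding="utf-8").strip().splitlines()
        assert lines[0] == (
            "notification_id,patient_id,event_type,t_mu,n_alarms,first_t_beta,last_t_beta"
        )
        assert len(lines) == 1 + 4
        assert lines[1] == "1,1,heart_rate,0,1,0,0"
        assert lines[2] == "2,1,heart_rate,4000,4,1000,4000"
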