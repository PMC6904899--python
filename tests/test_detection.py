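"""Threshold evaluation, alarm triggering, and stream parsing."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from quietward.detection import (
    detect,
    is_anomalous,
    read_routing_key_stream,
    read_stream,
    trigger_alarm,
)
from quietward.events import (
    ConfigError,
    Direction,
    NotificationPolicy,
    Reading,
    StreamParseError,
    ThresholdConfig,
)

THR_P1 = ThresholdConfig("1", "heart_rate", 60.0, 100.0)
THR_P5 = ThresholdConfig("5", "heart_rate", 50.0, 102.0)


class TestIsAnomalous:
    @pytest.mark.parametrize(
        "value, threshold, anomalous, direction",
        [
            (55.0, THR_P1, True, Direction.LOW),
            (60.0, THR_P1, False, Direction.NONE),   # boundary: equal to min is normal
            (100.0, THR_P1, False, Direction.NONE),  # boundary: equal to max is normal
            (80.0, THR_P1, False, Direction.NONE),
            (103.0, THR_P5, True, Direction.HIGH),
            (102.0, THR_P5, False, Direction.NONE),
            (49.999, THR_P5, True, Direction.LOW),
        ],
    )
    def test_strict_threshold_comparison(self, value, threshold, anomalous, direction):
        assert is_anomalous(value, threshold) == (anomalous, direction)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), float("-inf")])
    def test_nonfinite_rejected(self, bad):
        with pytest.raises(ValueError):
            is_anomalous(bad, THR_P1)

    @settings(derandomize=True, max_examples=200)
    @given(value=st.floats(min_value=-50.0, max_value=250.0, allow_nan=False))
    def test_equivalent_to_independent_redecision(self, value):
        # brute-force re-decision straight from the range definition
        expected = value < THR_P1.v_min or value > THR_P1.v_max
        anomalous, direction = is_anomalous(value, THR_P1)
        assert anomalous == expected
        assert (direction is not Direction.NONE) == expected

    @settings(derandomize=True, max_examples=100)
    @given(
        value=st.floats(min_value=100.0, max_value=200.0, allow_nan=False),
        bump=st.floats(min_value=0.0, max_value=100.0, allow_nan=False),
    )
    def test_monotone_above_max(self, value, bump):
        # once above v_max, raising the value never flips the decision back
        if is_anomalous(value, THR_P1)[0]:
            assert is_anomalous(value + bump, THR_P1)[0]


class TestDetect:
    def test_above_max_yields_anomaly_at_reading_time(self, patient1_cfg):
        event = detect(Reading("1", "heart_rate", 120.0, 5000), patient1_cfg)
        assert event is not None
        assert event.t_alpha == 5000
        assert event.direction is Direction.HIGH
        assert event.value == 120.0

    def test_in_range_reading_is_ignored(self, patient1_cfg):
        assert detect(Reading("1", "heart_rate", 80.0, 5000), patient1_cfg) is None

    def test_unconfigured_patient_is_config_error(self, patient1_cfg):
        with pytest.raises(ConfigError):
            detect(Reading("9", "heart_rate", 80.0, 0), patient1_cfg)


class TestTriggerAlarm:
    def _anomaly(self, patient1_cfg, t=5000):
        return detect(Reading("1", "heart_rate", 120.0, t), patient1_cfg)

    def test_zero_delay_default(self, patient1_cfg):
        alarm = trigger_alarm(self._anomaly(patient1_cfg), NotificationPolicy(300_000), 1)
        assert alarm.t_beta == 5000 and alarm.d_beta == 0

    def test_configured_triggering_delay(self, patient1_cfg):
        policy = NotificationPolicy(mni=300_000, d_beta_default=250)
        alarm = trigger_alarm(self._anomaly(patient1_cfg), policy, 1)
        assert alarm.t_beta == 5250

    @settings(derandomize=True, max_examples=100)
    @given(
        t_alpha=st.integers(min_value=0, max_value=10**7),
        d_beta=st.integers(min_value=0, max_value=10**5),
    )
    def test_delay_recomputed_from_events_equals_configured(self, t_alpha, d_beta):
        from quietward.events import AnomalyEvent

        anomaly = AnomalyEvent("1", "heart_rate", 120.0, t_alpha, Direction.HIGH)
        alarm = trigger_alarm(anomaly, NotificationPolicy(300_000, d_beta), 1)
        assert alarm.t_beta - alarm.anomaly.t_alpha == d_beta


class TestReadStream:
    def _write(self, tmp_path, text):
        path = tmp_path / "stream.csv"
        path.write_text(text, encoding="utf-8")
        return path

    def test_reads_rows_in_order(self, tmp_path):
        path = self._write(
            tmp_path,
            "time_ms,patient_id,sensor_type,value\n"
            "0,1,heart_rate,80\n1000,1,heart_rate,120.5\n",
        )
        readings = read_stream(path)
        assert [r.time for r in readings] == [0, 1000]
        assert readings[1].value == 120.5
        assert readings[0].patient_id == "1"

    def test_missing_value_rejected_with_line_number(self, tmp_path):
        path = self._write(
            tmp_path,
            "time_ms,patient_id,sensor_type,value\n0,1,heart_rate,80\n1000,1,heart_rate,\n",
        )
        with pytest.raises(StreamParseError, match="line 3"):
            read_stream(path)

    def test_time_regression_per_patient_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            "time_ms,patient_id,sensor_type,value\n"
            "1000,1,heart_rate,80\n0,1,heart_rate,81\n",
        )
        with pytest.raises(StreamParseError, match="decreases"):
            read_stream(path)

    def test_missing_column_rejected(self, tmp_path):
        path = self._write(tmp_path, "time_ms,patient_id,value\n0,1,80\n")
        with pytest.raises(StreamParseError, match="sensor_type"):
            read_stream(path)

    @pytest.mark.parametrize(
        "rule, expected", [("first", 80.0), ("mean", 81.0), ("last", 82.0)]
    )
    def test_downsample_to_one_reading_per_second(self, tmp_path, rule, expected):
        path = self._write(
            tmp_path,
            "time_ms,patient_id,sensor_type,value\n"
            "0,1,heart_rate,80\n400,1,heart_rate,81\n900,1,heart_rate,82\n"
            "1000,1,heart_rate,90\n",
        )
        readings = read_stream(path, downsample=rule)
        assert [r.time for r in readings] == [0, 1000]
        assert readings[0].value == expected
        assert readings[1].value == 90.0


class TestRoutingKeyStream:
    def test_patient_and_value_split_on_first_dot(self):
        readings = read_routing_key_stream(["16.88", "16.92.5"], interval_ms=1000)
        assert [(r.patient_id, r.value, r.time) for r in readings] == [
            ("16", 88.0, 0),
            ("16", 92.5, 1000),
        ]
        assert all(r.sensor_type == "heart_rate" for r in readings)

    def test_per_patient_clocks_and_merge_order(self):
        readings = read_routing_key_stream(["2.70", "1.80", "1.85"], interval_ms=500)
        assert [(r.patient_id, r.time) for r in readings] == [
            ("1", 0), ("2", 0), ("1", 500),
        ]

    def test_bad_line_rejected(self):
        with pytest.raises(StreamParseError):
            read_routing_key_stream(["no-dot-here"])
        with pytest.raises(StreamParseError):
            read_routing_key_stream(["3.notanumber"])
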