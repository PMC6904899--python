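"""Shared fixtures: reference configs and randomized stream suites.

The randomized suites are generated once per session from fixed seeds so
the property assertions (notification spacing, delay bounds, alarm
conservation, oracle equivalence) run over a stable population of
scenarios.  Suite sizes and time scales are chosen so the whole run stays
desk-fast: the engine suite uses 1 Hz sampling like the reference setup,
while the oracle suite shrinks intervals and MNI proportionally because
the reference simulator walks the clock millisecond by millisecond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from quietward.engine import EventLog, run, replay_oracle
from quietward.events import (
    ExperimentConfig,
    NotificationPolicy,
    ThresholdConfig,
)
from quietward.synth import (
    Direction,
    EpisodeSpec,
    StreamSpec,
    generate_stream,
    readings_from_frame,
)


@dataclass(frozen=True)
class StreamCase:
    """One randomized scenario: its config, spec, and replayed log."""

    cfg: ExperimentConfig
    spec: StreamSpec
    log: EventLog


def _random_episodes(rng: np.random.Generator, horizon: int, interval: int, max_eps: int):
    """Non-overlapping episodes: one per equal slot, random start/length."""
    n_eps = int(rng.integers(0, max_eps + 1))
    if n_eps == 0:
        return ()
    slot = horizon // n_eps
    episodes = []
    for i in range(n_eps):
        lo, hi = i * slot, (i + 1) * slot
        max_dur = max(interval, (hi - lo) // 2)
        duration = int(rng.integers(interval, max_dur + 1))
        start = int(rng.integers(lo, max(lo + 1, hi - duration)))
        episodes.append(
            EpisodeSpec(
                start=start,
                duration=duration,
                direction=Direction.HIGH if rng.random() < 0.5 else Direction.LOW,
                magnitude=float(rng.uniform(5.0, 25.0)),
            )
        )
    return tuple(episodes)


def _random_case(
    rng: np.random.Generator,
    *,
    interval_choices,
    n_range,
    mni_choices,
    max_eps: int,
) -> tuple[ExperimentConfig, StreamSpec]:
    v_min = float(rng.uniform(40.0, 70.0))
    v_max = v_min + float(rng.uniform(20.0, 60.0))
    patient = str(int(rng.integers(1, 8)))
    thr = ThresholdConfig(patient, "heart_rate", v_min, v_max)
    interval = int(rng.choice(interval_choices))
    n = int(rng.integers(*n_range))
    mni = int(rng.choice(mni_choices))
    spec = StreamSpec(
        patient_id=patient,
        sensor_type="heart_rate",
        baseline_mean=(v_min + v_max) / 2.0,
        baseline_sd=float(rng.uniform(0.0, (v_max - v_min) / 6.0)),
        interval=interval,
        n_readings=n,
        episodes=_random_episodes(rng, n * interval, interval, max_eps),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cfg = ExperimentConfig(
        number_of_wards=1,
        number_of_patients=1,
        number_of_sensors=1,
        sensors_reading_interval=interval,
        number_of_readings=n,
        thresholds={thr.key: thr},
        policy=NotificationPolicy(mni=mni),
    )
    return cfg, spec


def _materialize(cfg: ExperimentConfig, spec: StreamSpec) -> StreamCase:
    thr = cfg.threshold_for(spec.patient_id, spec.sensor_type)
    readings = readings_from_frame(generate_stream(spec, thr))
    return StreamCase(cfg=cfg, spec=spec, log=run(readings, cfg))


@pytest.fixture(scope="session")
def property_suite() -> list[StreamCase]:
    """200 randomized 1 Hz scenarios replayed through the engine."""
    rng = np.random.default_rng(20_240_901)
    cases = []
    for _ in range(200):
        cfg, spec = _random_case(
            rng,
            interval_choices=[1000],
            n_range=(200, 1200),
            mni_choices=[30_000, 60_000, 120_000, 300_000],
            max_eps=4,
        )
        cases.append(_materialize(cfg, spec))
    return cases


@pytest.fixture(scope="session")
def oracle_suite() -> list[tuple[ExperimentConfig, list, EventLog, EventLog]]:
    """100 small fast-clock scenarios replayed by both engine and oracle."""
    rng = np.random.default_rng(77_003)
    out = []
    for _ in range(100):
        cfg, spec = _random_case(
            rng,
            interval_choices=[20, 50, 100],
            n_range=(100, 400),
            mni_choices=[1_000, 2_500, 5_000, 12_000],
            max_eps=3,
        )
        thr = cfg.threshold_for(spec.patient_id, spec.sensor_type)
        readings = readings_from_frame(generate_stream(spec, thr))
        out.append((cfg, readings, run(readings, cfg), replay_oracle(readings, cfg)))
    return out


@pytest.fixture
def patient1_cfg() -> ExperimentConfig:
    """Single patient with the (60, 100) heart-rate range and 5-min MNI."""
    thr = ThresholdConfig("1", "heart_rate", 60.0, 100.0)
    return ExperimentConfig(
        number_of_wards=1,
        number_of_patients=1,
        number_of_sensors=1,
        sensors_reading_interval=1000,
        number_of_readings=60_000,
        thresholds={thr.key: thr},
        policy=NotificationPolicy(mni=300_000),
    )
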