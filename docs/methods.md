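# Methods

## Model and assumptions

`quietward` models alarm management as three event classes on a single
integer-millisecond clock: anomaly detection (α), alarm triggering (β)
and notification delivery (μ). A reading is anomalous iff strictly
outside its per-(patient, sensor) normal range `[v_min, v_max]`; values
equal to a limit are normal. Both comparisons are strict by construction
of the anomalous-value set, and the choice is pinned by unit tests.
Every anomalous sample raises its own anomaly and alarm — there is no
run-length merging at detection time — so alarm counts equal anomalous
sample counts exactly.

The reasoner enforces one delivery rule per (patient_id, alarm type) key:
consecutive notifications must be at least one minimum notification
interval (MNI) apart. Alarm type is the sensor parameter only
(`heart_rate`), not the violated side; low and high excursions of the
same parameter share one notification stream, with direction retained as
event metadata.

### Decision procedure

For an alarm triggered at `t_beta` with last notification at `t_mu_k`:

- `t_mu_k` absent (never notified) or `t_beta - t_mu_k >= MNI`, and no
  buffer open → immediate single-alarm notification at `t_mu = t_beta`
  (delay 0); boundary inclusive: a gap of exactly MNI delivers
  immediately.
- otherwise → the alarm joins the key's buffer. The first buffered alarm
  opens the buffer and fixes the release time at `t_mu_k + MNI`; later
  arrivals append without moving it. At release, the buffer becomes one
  grouped notification and `t_mu_k` advances to the release time.

"Never notified" is an explicit absent value rather than the zero
sentinel a time-arithmetic encoding would suggest; a genuine notification
at epoch 0 is therefore unambiguous.

Scheduling the release at `t_mu_k + MNI` (rather than a fixed span from
the first buffered alarm) makes both safety properties hold by
construction: spacing is exactly ≥ MNI, and each buffered alarm waits
`release_time - t_beta = MNI - LNP`, which is strictly inside (0, MNI)
whenever buffering occurs.

### Simultaneity

Within one timestamp the engine processes readings (and the alarms they
trigger) first, then alarms whose triggering delay expires, then buffer
releases. An alarm triggered exactly at a release instant therefore
joins the outgoing grouped notification with delay 0 instead of opening
a fresh buffer. The alternative order (release first) was rejected
because it hands that alarm a delay of exactly MNI, breaking the strict
delay bound. Consequence: a maximal contiguous run of `n ≥ 2`
per-interval alarms starting from an idle key yields exactly
`1 + ceil((n-1)·interval / MNI)` notifications, a closed form the test
suite verifies against the reference simulator rather than assumes.

One degenerate corner remains: if two same-key alarms shared one
millisecond and the first was delivered immediately, the second would
wait exactly MNI. With per-patient sampling at strictly increasing
timestamps — true of every stream this package generates or targets —
the situation cannot arise.

### End of stream

By default the clock drains all scheduled releases after the last
reading, so every alarm lands in exactly one notification and all bounds
hold. The `--flush-at-end` option instead emits residual buffers at the
last reading's time (or at the last contained alarm's trigger time, if a
triggering delay pushed it later); flushing shortens tail delays but is
off by default because it changes the delivery cadence.

## Parameters

| parameter | units | default | meaning |
|---|---|---|---|
| `v_min`, `v_max` | sensor units | per patient | normal range; strict limits |
| `mni` | ms | 300,000 | minimum gap between same-key notifications (5 min) |
| `d_beta_default` | ms | 0 | delay between detection and alarm triggering |
| `sensors_reading_interval` | ms | 1000 | sampling interval (generator/validators only; the engine tolerates irregular stamps) |
| `number_of_readings` | — | 60,000 | stream length of the packaged experiments |

The 5-minute MNI encodes the clinical judgment that heart-rate alarms in
the packaged scenarios may be delayed up to that period without
endangering the patient; the first alarm of any episode is always
delivered immediately regardless.

## Synthetic streams

The generator emulates the one statistical feature of real monitoring
data that the notification arithmetic depends on: long in-range
baselines punctuated by contiguous multi-minute anomalous episodes. The
baseline is Gaussian noise clipped strictly inside the normal range
(clipping rather than resampling keeps generation O(n) and exactly
reproducible); episodes hold the signal a fixed magnitude beyond the
violated threshold with uniform jitter bounded to half a magnitude, so
episode samples are always anomalous and baseline samples never are.
Alarm counts are therefore exact by construction and independent of the
seed, which only moves the noise.

The five packaged experiments share one scaffold — 1 ward, 1 patient,
1 heart-rate sensor, 1000 ms interval, 60,000 readings, MNI 5 min — and
differ in thresholds and episode layout. The anomalous-seconds totals
(407, 423, 308, 586, 204) are placed as one or two well-separated runs
(starts at 600 s and 3600 s) chosen so the replay collapses them to 4,
3, 3, 4 and 2 notifications respectively; the original episodes'
temporal positions are unpublished, so these layouts are count-faithful
synthetic stand-ins, not waveform reconstructions. What passing tests
show is that the pipeline reproduces the published alarm→notification
arithmetic under the stated conditions; they say nothing about artifact
rejection, sensor dropout, physiologic dynamics or multi-parameter
correlation, none of which the generator models.

## Evaluation metrics

Percentages are floor-truncated, not rounded: notified share =
trunc₁(100·notifications/alarms), reduction =
trunc₁(100·(alarms−notifications)/alarms). Truncation is pinned by the
586-alarm row, whose notified share 0.6826% displays as 0.6 (rounding
would give 0.7). The mean reduction pools alarms before dividing —
trunc₂(100·Σ(a−n)/Σa) — giving 99.17% for the five experiments
(1912/1928), and truncation is computed in exact integer arithmetic.
With zero alarms the ratios are reported as not-applicable rather than
zero. The audit checks four invariants on any log: same-key notification
spacing ≥ MNI, no alarm missing from every notification, no alarm
duplicated across notifications, and every per-alarm delay in [0, MNI).

## Verification strategy and problem sizes

Two independent routes are compared: the event-driven engine and a
reference simulator that advances the clock one millisecond at a time,
re-deriving every decision from the rule. The suites run at sizes chosen
to keep the whole test run desk-fast:

- engine property suite: 200 randomized 1 Hz scenarios, 200–1200
  readings, MNI 30 s–5 min, 0–4 episodes — audited for spacing, delay
  bounds, immediate first delivery and conservation;
- oracle-equivalence suite: 100 randomized fast-clock scenarios (20–100
  ms intervals, 100–400 readings, MNI 1–12 s) where engine and oracle
  logs must be identical event for event; the oracle refuses horizons
  beyond 10⁶ ms as a guard against accidental slow runs;
- the five packaged experiments replayed end to end (60,000 readings
  each) must reproduce their published rows exactly.

All randomness is seeded; hypothesis-based property tests run
derandomized.

## Known limitations

- Replay only: no real-time operation, transport, acknowledgment or
  escalation semantics.
- No false-alarm-probability labeling and no recipient selection; a
  notification is "delivered" when emitted.
- Thresholds are static per patient; no adaptive or trend-based
  detection, and readings with missing values are rejected at parse time
  rather than interpreted.
- The sub-second downsampling option (`first|mean|last` per second)
  exists for convenience; which rule a given clinical recording system
  applies is deployment-specific.
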