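# matbsim

A headless, seed-deterministic re-implementation of the Multi-Attribute
Task Battery (MATB) — the classic four-subtask aviation multitasking
platform used in human-performance, cognitive-workload and
trust-in-automation research — built as a simulation engine that runs
without a GUI, audio hardware, a joystick, or human subjects.

It is aimed at researchers who need the *logic* of the battery rather than
its screen: reliability-targeted adaptive automation, performance cueing,
forced automation handoffs, seeded experiment generation and
research-grade scored output, all exercised end-to-end by synthetic
operator agents so that every behavioural pathway is testable and exactly
reproducible from a handful of seeds.

## The battery

Four subtasks run concurrently on a fixed 0.05 s (~20 Hz) simulation loop,
plus a periodic subjective workload probe:

| task | kind | operator action | per-event/tick score |
|---|---|---|---|
| system monitoring | visual vigilance, 4 lights | press matching joystick button before timeout | `(timeout − RT)/timeout × 100` |
| communications | auditory vigilance (transcript stimuli) | select radio, channel, frequency while the active light is on | `(window − RT)/window × 100`, accuracy out of 3 elements |
| tracking | compensatory control | null the drifting cursor against the centre target | `deviation/range × 100` (error %), complement logged as performance |
| resource management | strategic fuel transfer, 6 tanks / 8 pumps | toggle pumps to hold both main tanks at 2,000 units | `(level − 2000)/range × 100`, signed, clamped to ±100 |

The workload probe is a modified Instantaneous Self-Assessment (ISA)
scale: every `interval` seconds a 1,000 Hz right-channel tone and a panel
light prompt the operator, who has 10 s to rate workload 1–10 before the
scale resets to 0; missed prompts are logged as explicitly missing.

## Reliability-targeted automation

Each subtask has an automation agent whose *reliability* R ∈ [0, 100] is
the normalized score the agent is tuned to achieve. Agents derive their
behavioural set-point from the task's scoring limit via

```
target_value = target_limit − R · target_limit / 100
```

so a system-monitoring agent at R = 75 with a 5 s timeout answers every
light (always correctly) at exactly 1.25 s, scoring 75 per event, and a
tracking agent at R = 50 holds the cursor on a ring at half the scoring
range. The resource-management agent is a banded controller (coast until
either |tank score| exceeds 100 − R, then drive every useful pump until
back inside a hysteresis band); its achieved score is a bound, not an
equality. On top of the agents sit performance *cueing* (prompt the
operator to enable automation when a moving-average score falls below a
threshold) and *forced handoffs* (automation imposed and locked against
revocation until a time or performance-stabilization release).

## Worked example

`python examples/reliability_sweep.py` runs the automated agents at four
reliability levels for 300 s each and prints:

```
task        target R  achieved
sysmon          25.0     25.00
comms           25.0     25.00
tracking        25.0     24.74
sysmon          50.0     50.00
comms           50.0     50.00
tracking        50.0     49.63
sysmon          75.0     75.00
comms           75.0     75.00
tracking        75.0     74.53
sysmon         100.0    100.00
comms          100.0    100.00
tracking       100.0     99.30
```

Every achieved mean equals the dialled-in reliability to within ±1: the
discrete-task agents hit it exactly (their reaction times are the
target value, which is tick-aligned here), while the tracking agent sits a
fraction low because random drift perturbs the cursor off its ring each
tick before the next correction.

`python examples/run_session.py` closes the loop with a human-like
stochastic operator (lognormal latencies, 95 % button accuracy, noisy
proportional tracking, banded pump heuristic) and prints the session
summary — e.g. `sysmon_score: 57.45` (≈1.5 s mean latency worth ≈70,
dragged down by misses scoring 0), `comms_accuracy: 96.67` (per-element
accuracy of the responses), `rm_tank1_score: −28.31` (the main tanks ride
somewhat below the 2,000-unit target between the operator's periodic pump
checks), `workload_value: 4.10` (mean 1–10 rating, rising with concurrent
task load).

Other examples: `schedule_demo.py` (seeded generation + demand
transition), `cvd_palette.py` (colour-vision-deficiency simulation of a
panel palette).

## Command line

```bash
matbsim generate --config exp.yaml --seed 7 --out schedule.csv   # event placement
matbsim run --config exp.yaml --operator op.yaml --out results/  # full session
matbsim selftest                                                 # reliability recovery check
```

`run` writes four files: `*_raw.csv` (one row per tick, frozen column
registry), `*_markers.csv` (event marker stream), `*_summary.csv`
(per-section and whole-session means) and `*_meta.json` (seeds, tick
count, mean wall-clock loop time).

## Configuration

A session is one YAML file; `duration` is the only required key.

```yaml
duration: 300.0          # s
tick_dt: 0.05            # s, simulation step
master_seed: 42
demand: {sysmon: 2, comms: 2, resman: 2}    # ordinal levels -> events/min table
sysmon: {timeout: 5.0}
comms: {timeout: 10.0, stimulus_duration: 4.0, confederate_rate: 0.25,
        own_callsign: "NASA 504"}
tracking: {range: 100.0, speed_level: 2, invert_x: false,
           orientation: cursor-to-target}
resman: {range: 1000.0, drain_rate: 600.0, pump_failure_duration: 15.0}
workload: {interval: 30.0, window: 10.0}
automation:
  sysmon: {enabled: true, reliability: 75.0}
  tracking: {cue_threshold: 50.0,
             forced_windows: [{time: 120.0, duration: 60.0}]}
```

Unknown keys are rejected; every bound violation names the offending
field. Operator specs use the same dialect
(`{type: stochastic, seed: 3, params: {...}}`).

## Communications transcript grammar

Audio playback is out of scope; stimuli are transcript events with the
semantics of the spoken calls:

```
transcript ::= callsign ", " callsign ", turn your " radio " radio to " channel "." frequency "."
callsign   ::= word (" " word)*          ; both occurrences identical
radio      ::= "NAV1" | "NAV2" | "COM1" | "COM2"
channel    ::= 3 digits                  ; spoken before "point"
frequency  ::= 3 digits                  ; spoken after "point"
```

e.g. `NASA 504, NASA 504, turn your NAV1 radio to 126.475.` parses to
(NASA 504, NAV1, 126, 475).

## Marker vocabulary

`Start`, `Stop`, `SYSMON`, `COM`, `RM_FAILURE`, `RM_SHUTOFF`, `WORKLOAD`,
`SECTION`, and per task `AUTO_<TASK>_ON/OFF`, `CUE_<TASK>_ON/OFF`,
`FORCED_<TASK>_ON`, `FORCED_<TASK>_RELEASED`,
`TOGGLE_REJECTED_<TASK>`. Markers and per-tick scores can also be pushed
live to any object implementing the `StreamSink` contract
(`push(time, channel, value)`), the hook point for external
data-synchronization pipelines.

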