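# Methods

This note documents the models inside `matbsim`, the conventions and
defaults they ship with, why the open design choices were made the way
they were, and what the synthetic-operator tests do and do not establish
about real human data.

## Simulation loop

The engine advances simulated time on a fixed step `tick_dt`
(default 0.05 s, matching the ~20 Hz loop rate typical of desktop task
batteries). Simulated time is fully decoupled from the wall clock: the
loop runs as fast as the host allows, and an optional `realtime` flag
merely sleeps to ~1× pacing without affecting any result. Within a tick
the update order is fixed and documented, because a deterministic battery
needs a total order even where the original's loop diagram leaves it open:

1. activate scheduled events due in `(t_prev, t]`;
2. apply operator inputs;
3. apply automation inputs;
4. physics and timeouts (control + drift, fuel flows and drains,
   light/call/probe expiry);
5. scoring (per-tick continuous scores; per-event completions; both feed
   the automation moving-average windows);
6. cueing and forced-handoff evaluation;
7. append the log row (automation-state columns therefore reflect any
   stage-6 transition at the same tick).

Placing automation input after operator input (stage 3 after 2) means an
automation agent answering at its target time wins ties against an expiry
at the same tick, which keeps the reliability identity exact at R = 0.
Event onsets snap to the next tick boundary and per-event reaction times
are measured from that boundary, so agent reaction times are exact
multiples of `tick_dt` and tick-aligned target values (e.g. 1.25 s at
R = 75, timeout 5 s) are achieved without quantization error.

A session is a pure function of `(config, master_seed, operator seed)`.
Every stochastic component draws from a named child stream of the master
seed (CRC-32 of the stream name as the spawn key of a
`numpy.random.SeedSequence`), so enabling or re-parameterizing one
component never perturbs another's randomness. The recorded mean
wall-clock loop time — the one non-deterministic observable — lives in the
metadata JSON, keeping the raw/marker/summary CSVs byte-identical across
replays.

## Event scheduling

The generator places the demanded number of events per task uniformly at
random subject to a per-task minimum separation (system monitoring: the
light timeout; communications: stimulus duration + timeout; pump failures:
the failure duration; shutoffs: a fixed 10 s spacing). Cross-task overlap
is deliberately allowed — concurrent demands are the point of a
multitasking battery. Placement uses the exact *gap construction*: draw
`n` uniforms on `[0, L − (n−1)s]`, sort, and add `i·s`. This samples
precisely the uniform distribution conditioned on all gaps ≥ s — the same
law naive rejection sampling converges to — but is O(n log n), cannot fail
spuriously, and turns an impossible request into an immediate capacity
error instead of a silent truncation or a hang.

Demand levels are an explicit events-per-minute table in the config (no
standard mapping exists across battery versions); level 0 is empty, levels
1–3 default to 2/4/8 lights, 1/2/3 calls and 0.5–2 pump events per minute.
The level-3 call rate is capped by feasibility: each call occupies a 14 s
exclusive window by default, bounding how many can fit per minute.
Distractor (confederate-callsign) calls are *added on top of* the demanded
own-callsign count at `confederate_rate` (a demanded call is something the
operator must answer; distractors are extra load, and folding them into
the count would make "10 events" mean different response workloads at
different rates). Workload prompts are periodic, not randomized: at
`k·interval` for `k = 1..floor(duration/interval)` (no prompt at t = 0),
with the final prompt pulled back just enough for its response window to
fit inside the session.

Demand transitions append a freshly generated segment after an existing
schedule, offsetting onsets and recording a section boundary; base events
are reused untouched, and the summary reports per-section means delimited
by those boundaries.

## Scoring conventions

Reaction-time tasks score `(limit − RT)/limit × 100` against their
timeout; misses score 0 and count against accuracy, as does every
wrong-button press (a wrong press never cancels the light it missed).
Communications accuracy is the number of correct elements out of three
(radio, channel, frequency); the reaction time — and hence a nonzero
score — exists only for a fully correct response, and reaction time is
measured from stimulus *onset* by default (`rt_reference: offset`
switches to stimulus end; the choice is a convention, so it is
configurable and logged).

Tracking logs **two** columns on purpose: `tracking_score`
(deviation/range × 100, the raw error percentage, which *rises* with poor
tracking) and `tracking_performance` (its complement). Every other task's
score rises with quality, and the reliability identity "achieved score =
R" only holds uniformly on a higher-is-better index, so automation
targeting and cueing use the performance column while the error percentage
remains available for analyses that expect it. They always sum to 100.

Resource-management tank scores are signed percentages
`(level − 2000)/range × 100` clamped to ±100; 0 is on target. The
automation performance fed to cueing for this task is
`100 − (|s₁| + |s₂|)/2`.

## Automation

`target_value(limit, R) = limit − R·limit/100` maps a reliability to a
behavioural set-point. The system-monitoring and communications agents
respond with guaranteed accuracy exactly when an event's age reaches the
target value (all three communication elements entered in the same loop
iteration); distractor calls are ignored. The tracking agent steers the
cursor each tick onto a ring of radius `target_value(range, R)` around the
target, correcting the previous tick's drift; its achieved mean sits a few
tenths below R because the drift increment lands after the correction.

The resource-management agent is a banded threshold controller: it lets
the tank scores coast until either |score| exceeds the trigger band
(100 − R), then activates every pump that moves the offending tank toward
the target (supply-to-main inflows; main-to-main transfers when one tank
is high and the other low) and shuts opposing ones, until both scores are
back inside `hysteresis_fraction` (default 0.5) of the band. Supply tanks
are topped up from the infinite tanks whenever below 90 % capacity. Its
long-run |score| is bounded by the band plus a small per-tick overshoot —
an intentional bound rather than an equality, since drains and tank
limits preclude exact score servoing.

Cueing compares a sliding moving-average score (window default 30 s,
holding its last value through event gaps) against `cue_threshold`; the
cue is active only while automation is off, and transitions emit markers.
Forced handoffs trigger at scheduled times or when the moving average
falls below `forced_perf_threshold`; while forced, operator toggles are
rejected and logged. Release occurs when the time lock expires or when
the moving average has stayed at or above the release threshold for
`release_dwell` (default 10 s) continuously; release clears the lock but
leaves automation enabled, so disabling it afterwards is an explicit
operator act. The "performance has stabilized" rule is evaluated on the
task's moving-average score regardless of who (operator or agent) produced
it, which is the only observable the engine has.

Per-activation reliability epochs arrive through the schedule, so a
progressively failing or improving automation is a list of
`(time, reliability)` pairs in the config.

## Resource-management physics

Six tanks in the classic layout: mains A and B (capacity 4,000, start
2,000, drain 600 units/min each), limited supplies C and D (capacity
2,000, start 1,000), infinite E and F. Eight pumps,
`C→A, E→A, D→B, F→B, E→C, F→D, A→B, B→A`, at
800/600/800/600/600/600/400/400 units/min — supply-tank pumps faster than
infinite-tank pumps. All of these are shipped artifact defaults (only the
2,000-unit target, the 1,000-unit supply start and the six-tank /
eight-pump structure are fixed by the task definition) and every one is
overridable, including the topology.

Flows are resolved simultaneously per tick: each active, un-failed pump
requests `rate·dt/60`, requests are scaled pro rata per source (scarce
fuel splits proportionally) and then per destination (headroom likewise),
so the result is order-independent within a tick and fuel is conserved to
machine precision — the engine keeps explicit inflow/drain ledgers that
tests audit tick-by-tick. Failures switch a pump off and lock it until
expiry; shutoffs switch it off but leave it toggleable.

## Tracking drift

Drift is a random walk on velocity: zero-mean Gaussian increments of
standard deviation `5·speed_level·√dt` grid-units/s, a speed cap of
`10·speed_level` units/s, position reflected at the ±range grid edges.
Speed level 0 disables drift. The walk has no preferred direction;
long-run mean displacement is near zero (verified by Monte-Carlo in the
suite). Control input in [−1, 1]² moves the controlled entity at
`gain·control` (default gain 200 units/s full deflection); axis inversion
and the reversed task orientation (control moves the target square
instead of the cursor) change only which entity moves, never the
deviation math.

## Workload probe

Modified ISA: valid ratings are 1–10; the idle scale displays 0, and 0 is
*never* a recorded response — missed prompts are an explicit missing
sentinel, because conflating "rated 0" with "did not answer" would corrupt
any workload analysis downstream. Prompt tone: a right-channel-only
sinusoid at 1,000 Hz, synthesized at any sample rate above Nyquist and
writable as 16-bit PCM WAV via the standard library.

## Colour profiles and CVD simulation

Colour assignments are cosmetic (task state is boolean/numeric), but the
profile carries a colour-vision-deficiency simulation: sRGB decode → 3×3
matrix → sRGB encode, clipped to gamut. The shipped matrices are the
severity-1.0 protan/deutan/tritan transforms of the physiologically-based
Machado–Oliveira–Fernandes model, stored as package data so researchers
can substitute intermediate severities. The matrix stage is linear by
construction; the end-to-end map is not (gamma), which is why the
homogeneity property is stated and tested on the linear stage.

## Synthetic operators

Operators see only an `ObservableState` mirroring the display — light
states, the heard stimulus, cursor and target, tank levels and pump
states, open prompts, cues and automation switches — never schedule
futures or internal engine state. The stochastic operator uses lognormal
response latencies (parameterized by mean and coefficient of variation),
Bernoulli button/element accuracy, noisy proportional tracking control, a
periodic banded pump heuristic, and a workload rating linear in the
concurrent discrete task load, clipped to 1–10. These are behavioural
stand-ins chosen so that every pathway (hits, misses, wrong buttons,
partial responses, distractor errors, late ratings, automation toggles)
occurs with controllable frequency.

What passing tests show: the scoring pipeline, automation logic, schedule
and logging behave exactly as specified under agents whose ground truth is
known. What they do not show: anything about human parameter values —
the latency means, accuracy rates and control gains are plausible but not
fitted to data, and no claim is made that the stochastic operator predicts
human scores.

## Problem sizes and numerical notes

The reliability-recovery checks and the acceptance measurements use 300 s
sessions at `tick_dt` 0.05 s (6,000 ticks) with 20 system-monitoring
events and a 30 s transient discarded for tracking steady state — large
enough that per-event means are stable to well under the ±1 tolerance,
small enough to run in seconds. Comparisons against event onsets and
window ends use a 1e-9 absolute guard; scores at exact boundaries (RT =
timeout, deviation = range, level at ±range) take the closed-interval
value (0, 100, ±100 respectively). CSVs serialize at full double
precision and are read back with round-trip float parsing.

## Known limitations

- No rendering, audio playback, or joystick I/O; stimuli are semantic
  events and inputs arrive from operator models (or any code driving
  `Engine.step`).
- Live streaming is an abstract sink contract; no network transport is
  bundled.
- The resource-management automation targets a score *band*; do not
  expect `achieved == R` for that task.
- The stochastic operator is not a cognitive model; use it to exercise
  the battery, not to simulate findings.
- Background-chatter mode represents chatter as no-response noise events;
  it does not model acoustic masking of own-callsign calls.
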