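"""Seeded automatic placement of discrete events over a session.

Given a validated configuration, the generator places the requested number
of events for each task uniformly at random subject to a per-task minimum
separation, so that no two events of the same task overlap (cross-task
overlap is deliberately permitted — concurrent demands are what make the
battery a multitasking load).  Placement is a pure function of
(config, master seed): publishing parameter settings plus the seed lets
another lab replicate the exact event placement.

Placement uses the exact gap construction: to place n onsets with minimum
separation s in [0, L], draw n uniform points in [0, L - (n-1)s], sort
them, and add i*s to the i-th.  This samples exactly the uniform
distribution conditioned on all gaps >= s (the same law rejection sampling
converges to) and fails fast with a capacity error when the request cannot
fit.

Each task draws from its own named child stream of the master seed, so
changing the demand of one task never perturbs another's placement.
Resource-management failures and shutoffs are placed as two separate
substreams (separation = failure duration, and a fixed spacing constant,
respectively) and merged under the "resman" task, so a shutoff may land
near a failure — only like events are kept apart.

Workload prompts are periodic, not randomized: one prompt every
``interval`` seconds starting at t = interval (the t = 0 prompt is
suppressed), ``floor(duration / interval)`` prompts in total, with the
final prompt pulled back just enough for its response window to fit inside
the session.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import child_rng
from .comms import RADIOS
from .config import SimulationConfig

__all__ = ["ScheduledEvent", "EventSchedule", "CapacityError",
           "generate_schedule", "append_schedule", "schedule_summary",
           "export_schedule", "import_schedule", "place_events"]

TASKS = ("sysmon", "comms", "resman", "workload", "automation")

#: Minimum separation between scheduled shutoffs (artifact constant; the
#: shutoff itself is instantaneous, this just spreads the disruptions).
SHUTOFF_SEPARATION = 10.0

DISTRACTOR_CALLSIGNS = ("NASA 407", "NASA 623", "NASA 719", "EAGLE 210")


class CapacityError(ValueError):
    """Requested events cannot fit with the required separation."""


@dataclass(frozen=True)
class ScheduledEvent:
    onset: float
    task: str       # one of TASKS
    payload: dict

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class EventSchedule:
    events: list[ScheduledEvent]
    seed: int
    duration: float
    section_boundaries: list[float] = field(default_factory=list)

    def for_task(self, task: str) -> list[ScheduledEvent]:
        return [e for e in self.events if e.task == task]


def place_events(n: int, duration: float, separation: float, event_length: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Place ``n`` onsets in [0, duration - event_length] with min separation.

    Raises :class:`CapacityError` when the request cannot fit; never
    silently truncates.
    """
    if n == 0:
        return np.empty(0)
    usable = duration - event_length
    slack = usable - (n - 1) * separation
    if usable < 0 or slack < 0:
        raise CapacityError(
            f"{n} events with separation {separation}s and length {event_length}s "
            f"cannot fit in {duration}s")
    pts = np.sort(rng.uniform(0.0, slack, size=n))
    return pts + separation * np.arange(n)


def _sysmon_events(config: SimulationConfig, n: int) -> list[ScheduledEvent]:
    rng = child_rng(config.master_seed, "schedule.sysmon")
    onsets = place_events(n, config.duration, config.sysmon.timeout,
                          config.sysmon.timeout, rng)
    lights = rng.integers(1, config.sysmon.n_lights + 1, size=n)
    return [ScheduledEvent(float(t), "sysmon", {"light": int(light)})
            for t, light in zip(onsets, lights)]


def _comms_events(config: SimulationConfig, n_own: int) -> list[ScheduledEvent]:
    cc = config.comms
    rng = child_rng(config.master_seed, "schedule.comms")
    # distractor calls are added on top of the demanded own-callsign count
    n_distract = round(n_own * cc.confederate_rate)
    n = n_own + n_distract
    window = cc.total_window
    onsets = place_events(n, config.duration, window, window, rng)
    own_flags = np.zeros(n, dtype=bool)
    own_flags[rng.choice(n, size=n_own, replace=False)] = True
    events = []
    for t, is_own in zip(onsets, own_flags):
        if not is_own and cc.chatter_mode:
            payload = {"noise": True}
        else:
            callsign = (cc.own_callsign if is_own
                        else DISTRACTOR_CALLSIGNS[int(rng.integers(len(DISTRACTOR_CALLSIGNS)))])
            payload = {
                "callsign": callsign,
                "is_own": bool(is_own),
                "radio": RADIOS[int(rng.integers(len(RADIOS)))],
                "channel": int(rng.integers(100, 1000)),
                "frequency": int(rng.integers(0, 1000)),
            }
        events.append(ScheduledEvent(float(t), "comms", payload))
    return events


def _resman_events(config: SimulationConfig, n_fail: int, n_shut: int) -> list[ScheduledEvent]:
    rng = child_rng(config.master_seed, "schedule.resman")
    dur = config.resman.pump_failure_duration
    fails = place_events(n_fail, config.duration, dur, dur, rng)
    shuts = place_events(n_shut, config.duration, SHUTOFF_SEPARATION, 0.0, rng)
    events = [ScheduledEvent(float(t), "resman",
                             {"pump": int(rng.integers(1, 9)), "kind": "failure",
                              "duration": dur})
              for t in fails]
    events += [ScheduledEvent(float(t), "resman",
                              {"pump": int(rng.integers(1, 9)), "kind": "shutoff"})
               for t in shuts]
    return events


def _workload_events(config: SimulationConfig) -> list[ScheduledEvent]:
    wl = config.workload
    n = int(config.duration / wl.interval + 1e-9)
    onsets = [k * wl.interval for k in range(1, n + 1)]
    if onsets and onsets[-1] > config.duration - wl.window:
        onsets[-1] = config.duration - wl.window
    return [ScheduledEvent(float(t), "workload", {"prompt": k + 1})
            for k, t in enumerate(onsets)]


def _automation_events(config: SimulationConfig) -> list[ScheduledEvent]:
    events = []
    for task in ("sysmon", "comms", "tracking", "resman"):
        auto = config.automation.for_task(task)
        if auto.enabled:
            events.append(ScheduledEvent(0.0, "automation",
                                         {"task": task, "action": "enable"}))
        for epoch in auto.reliability_epochs:
            events.append(ScheduledEvent(epoch.time, "automation",
                                         {"task": task, "action": "reliability",
                                          "reliability": epoch.reliability}))
        for fw in auto.forced_windows:
            events.append(ScheduledEvent(fw.time, "automation",
                                         {"task": task, "action": "forced",
                                          "duration": fw.duration}))
    return events


def generate_schedule(config: SimulationConfig) -> EventSchedule:
    """Place all discrete events for one session.  Pure in (config, seed)."""
    counts = config.demand.counts_for(config.duration)
    events = (_sysmon_events(config, counts.sysmon)
              + _comms_events(config, counts.comms)
              + _resman_events(config, counts.resman_failures, counts.resman_shutoffs)
              + _workload_events(config)
              + _automation_events(config))
    events.sort(key=lambda e: (e.onset, e.task))
    return EventSchedule(events=events, seed=config.master_seed,
                         duration=config.duration)


def append_schedule(base: EventSchedule, config2: SimulationConfig) -> EventSchedule:
    """Append a newly generated segment after ``base`` (a demand transition).

    New events are offset by the base duration and a section boundary is
    recorded at the junction; the base segment's events are reused
    untouched.
    """
    segment = generate_schedule(config2)
    shifted = [replace(e, onset=e.onset + base.duration) for e in segment.events]
    return EventSchedule(
        events=list(base.events) + shifted,
        seed=base.seed,
        duration=base.duration + segment.duration,
        section_boundaries=list(base.section_boundaries) + [base.duration],
    )


def schedule_summary(schedule: EventSchedule) -> pd.DataFrame:
    """Per-task counts and inter-event-gap statistics (for QC, not plotting)."""
    rows = []
    for task in TASKS:
        onsets = sorted(e.onset for e in schedule.for_task(task))
        gaps = np.diff(onsets) if len(onsets) > 1 else np.empty(0)
        rows.append({
            "task": task,
            "count": len(onsets),
            "min_gap": float(gaps.min()) if gaps.size else np.nan,
            "mean_gap": float(gaps.mean()) if gaps.size else np.nan,
        })
    return pd.DataFrame(rows).set_index("task")


def export_schedule(schedule: EventSchedule, path) -> None:
    """Write the schedule as a plain-text table (onset, task, payload JSON)."""
    df = pd.DataFrame({
        "onset": [e.onset for e in schedule.events],
        "task": [e.task for e in schedule.events],
        "payload": [json.dumps(e.payload, sort_keys=True) for e in schedule.events],
    })
    header = (f"# matbsim schedule v1 seed={schedule.seed} "
              f"duration={schedule.duration!r} "
              f"boundaries={json.dumps(schedule.section_boundaries, separators=(',', ':'))}\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def import_schedule(path) -> EventSchedule:
    """Read a schedule table written by :func:`export_schedule`."""
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("# matbsim schedule v1"):
            raise ValueError(f"{path} is not a matbsim schedule table")
        meta = dict(kv.split("=", 1) for kv in header[len("# matbsim schedule v1 "):].strip().split(" "))
        df = pd.read_csv(fh)
    events = [ScheduledEvent(float(r.onset), str(r.task), json.loads(r.payload))
              for r in df.itertuples()]
    return EventSchedule(events=events, seed=int(meta["seed"]),
                         duration=float(meta["duration"]),
                         section_boundaries=list(json.loads(meta["boundaries"])))
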