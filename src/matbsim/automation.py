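"""Reliability-targeted automation, performance cueing and forced handoffs.

Each of the four subtasks has an automation agent that, when enabled,
performs the task at an experimenter-set *reliability* — a target
normalized score between 0 and 100 that the agent is tuned to achieve.
The agent derives its behavioural set-point from the task's scoring bound
via the target-value relation

    target_value = target_limit - reliability * target_limit / 100

so that a discrete-task agent responding exactly at ``target_value``
seconds (of a ``target_limit``-second timeout) earns precisely the
reliability as its reaction-time score, and a tracking agent holding the
cursor on a ring of radius ``target_value`` (of a ``target_limit``-unit
range) earns the reliability as its performance index.  Discrete-task
agents are always 100% accurate; only their timing is degraded.

The resource-management agent is a banded controller: it lets the signed
tank scores coast until either magnitude exceeds ``100 - reliability``,
then turns on every pump that moves the offending tank back toward the
2,000-unit target until both scores re-enter a hysteresis band.  Its
achieved score is a bound, not an equality — the task's drain dynamics
make exact score servoing unrealistic.

The module also houses performance cueing (prompt the operator to enable
automation when a task's moving-average score falls below a threshold)
and forced handoffs (automation imposed without operator consent and
locked against revocation until a time or performance-stabilization
release fires).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .comms import CommResponse, CommsTaskState
from .config import AutomationTaskConfig
from .resman import LIMITED_TANKS, MAIN_TANKS, ResmanState, resman_score
from .sysmon import SysmonState
from .tracking import TrackingState

__all__ = ["target_value", "TaskAutomation", "auto_sysmon", "auto_comms",
           "auto_tracking", "auto_resman", "cue_update", "forced_handoff_update"]

_EPS = 1e-9


def target_value(limit: float, reliability: float) -> float:
    """Behavioural set-point for a reliability level against a scoring limit.

    ``limit - reliability * limit / 100``: 0 at reliability 100 (perfect,
    instantaneous automation), the full limit at reliability 0.
    """
    if limit <= 0:
        raise ValueError("target limit must be positive")
    if not 0 <= reliability <= 100:
        raise ValueError(f"reliability {reliability} outside [0, 100]")
    return limit - reliability * limit / 100.0


@dataclass
class TaskAutomation:
    """Automation state for one subtask."""

    task: str
    enabled: bool = False
    reliability: float = 100.0
    cue_threshold: Optional[float] = None
    cue_active: bool = False
    forced: bool = False
    locked_until: Optional[float] = None   # None while forced => stabilization release
    forced_perf_threshold: Optional[float] = None
    release_threshold: Optional[float] = None
    release_dwell: float = 10.0
    perf_window: float = 30.0
    hysteresis_fraction: float = 0.5
    corrective: bool = False               # resman banded-controller mode
    _samples: deque = field(default_factory=deque)   # (t, score)
    _last_avg: Optional[float] = None
    _stable_since: Optional[float] = None
    rejected_toggles: list[tuple[float, bool]] = field(default_factory=list)

    @classmethod
    def from_config(cls, task: str, cfg: AutomationTaskConfig) -> "TaskAutomation":
        return cls(task=task, enabled=cfg.enabled, reliability=cfg.reliability,
                   cue_threshold=cfg.cue_threshold,
                   forced_perf_threshold=cfg.forced_perf_threshold,
                   release_threshold=cfg.release_threshold,
                   release_dwell=cfg.release_dwell, perf_window=cfg.perf_window,
                   hysteresis_fraction=cfg.hysteresis_fraction)

    # -- performance tracking ------------------------------------------------

    def record_performance(self, t: float, score: float) -> None:
        """Feed one performance sample (0..100) into the sliding window."""
        self._samples.append((t, score))
        cutoff = t - self.perf_window
        while self._samples and self._samples[0][0] < cutoff:
            self._samples.popleft()

    def moving_average(self) -> Optional[float]:
        """Sliding-window mean score; holds its last value through gaps."""
        if self._samples:
            self._last_avg = float(np.mean([s for _, s in self._samples]))
        return self._last_avg

    # -- operator interaction ------------------------------------------------

    def request_toggle(self, desired: bool, t: float) -> bool:
        """Operator toggle attempt; rejected (and logged) while forced."""
        if self.forced:
            self.rejected_toggles.append((t, desired))
            return False
        self.enabled = desired
        return True

    def force(self, t: float, duration: Optional[float]) -> None:
        """Impose automation: enable and lock operator revocation."""
        self.enabled = True
        self.forced = True
        self.locked_until = None if duration is None else t + duration
        self._stable_since = None


# ---------------------------------------------------------------------------
# Per-task agents
# ---------------------------------------------------------------------------

def auto_sysmon(auto: TaskAutomation, state: SysmonState, t: float) -> list[int]:
    """Buttons to press now: each active light whose age reached the target.

    Always the correct button, never early — reaction time equals the
    target value (up to tick quantization), so the per-event score equals
    the reliability.
    """
    if not auto.enabled:
        return []
    delay = target_value(state.timeout, auto.reliability)
    return [light for light in state.active_lights
            if t - state.light_onset[light - 1] >= delay - _EPS]


def auto_comms(auto: TaskAutomation, state: CommsTaskState,
               t: float) -> Optional[CommResponse]:
    """Full, correct response once the active own-call's age reaches target.

    All three elements are entered in the same simulation step; distractor
    calls are ignored.
    """
    if not auto.enabled or state.active is None:
        return None
    ev = state.active
    if not ev.is_own or ev.is_noise:
        return None
    if state.response.complete():
        return None
    if t - ev.onset >= target_value(ev.total_window, auto.reliability) - _EPS:
        return CommResponse(radio=ev.radio, channel=ev.channel,
                            frequency=ev.frequency, completed_at=t)
    return None


def auto_tracking(auto: TaskAutomation, state: TrackingState, dt: float,
                  gain: float) -> Optional[np.ndarray]:
    """Control vector holding the cursor on a ring around the target.

    The ring radius is ``target_value(range, reliability)``: at reliability
    100 the cursor is driven onto the target; at 50 it is held at half the
    scoring range, yielding a deviation score of 50.
    """
    if not auto.enabled:
        return None
    radius = target_value(state.range, auto.reliability)
    offset = state.position - state.target
    dist = np.linalg.norm(offset)
    direction = offset / dist if dist > _EPS else np.array([1.0, 0.0])
    desired = state.target + radius * direction
    control = (desired - state.position) / (gain * dt)
    return np.clip(control, -1.0, 1.0)


def _classify_pumps(state: ResmanState):
    inflow: dict[str, list[int]] = {name: [] for name in MAIN_TANKS}
    transfer: list[tuple[int, str, str]] = []
    supply: list[tuple[int, str]] = []
    for p in state.pumps.values():
        if p.destination in MAIN_TANKS and p.source not in MAIN_TANKS:
            inflow[p.destination].append(p.id)
        elif p.source in MAIN_TANKS and p.destination in MAIN_TANKS:
            transfer.append((p.id, p.source, p.destination))
        elif p.destination in LIMITED_TANKS:
            supply.append((p.id, p.destination))
    return inflow, transfer, supply


def auto_resman(auto: TaskAutomation, state: ResmanState, t: float) -> list[int]:
    """Pump toggles for the banded resource-management controller.

    Tank scores may coast until either magnitude exceeds the trigger band
    ``100 - reliability``; the controller then activates every pump moving
    the offending tank toward the target (and shuts opposing pumps) until
    both scores are back inside ``hysteresis_fraction`` of the band.
    Supply tanks are topped up from the infinite tanks throughout.
    """
    if not auto.enabled:
        return []
    band = 100.0 - auto.reliability
    scores = {name: resman_score(state.tanks[name].level, state.target_level,
                                 state.range) for name in MAIN_TANKS}
    worst = max(abs(s) for s in scores.values())
    if not auto.corrective and worst > band:
        auto.corrective = True
    elif auto.corrective and worst <= auto.hysteresis_fraction * band:
        auto.corrective = False

    inflow, transfer, supply = _classify_pumps(state)
    desired_on: set[int] = set()
    if auto.corrective:
        for name in MAIN_TANKS:
            if scores[name] < 0:
                desired_on.update(inflow[name])
        for pid, src, dst in transfer:
            if scores[src] > 0 and scores[dst] < 0:
                desired_on.add(pid)
    for pid, dst in supply:
        tank = state.tanks[dst]
        if tank.capacity is not None and tank.level < 0.9 * tank.capacity:
            desired_on.add(pid)

    toggles = []
    for p in state.pumps.values():
        if p.failed(t):
            continue
        if p.on != (p.id in desired_on):
            toggles.append(p.id)
    return toggles


# ---------------------------------------------------------------------------
# Cueing and forced handoffs
# ---------------------------------------------------------------------------

def cue_update(auto: TaskAutomation, t: float) -> Optional[bool]:
    """Re-evaluate the performance cue; returns the new state on transition.

    The cue flashes while the task's moving-average score sits below the
    configured threshold and automation is not already on, and clears once
    the average recovers beyond it.
    """
    if auto.cue_threshold is None:
        return None
    avg = auto.moving_average()
    new = (avg is not None) and (avg < auto.cue_threshold) and not auto.enabled
    if new != auto.cue_active:
        auto.cue_active = new
        return new
    return None


def forced_handoff_update(auto: TaskAutomation, t: float) -> Optional[str]:
    """Evaluate forced-handoff triggers and releases.

    Performance triggers fire when the moving average drops below the
    configured threshold (release then requires the average to stay at or
    above the release threshold for the dwell period).  Time-locked
    handoffs release when the lock expires.  Release clears the lock but
    leaves automation enabled — the operator may then turn it off.
    Returns "forced" or "released" on a transition.
    """
    avg = auto.moving_average()
    if not auto.forced:
        if (auto.forced_perf_threshold is not None and avg is not None
                and avg < auto.forced_perf_threshold):
            auto.force(t, None)
            return "forced"
        return None
    if auto.locked_until is not None:
        if t >= auto.locked_until:
            auto.forced = False
            auto.locked_until = None
            return "released"
        return None
    threshold = (auto.release_threshold if auto.release_threshold is not None
                 else auto.forced_perf_threshold)
    if threshold is None or avg is None or avg < threshold:
        auto._stable_since = None
        return None
    if auto._stable_since is None:
        auto._stable_since = t
    if t - auto._stable_since >= auto.release_dwell:
        auto.forced = False
        auto._stable_since = None
        return "released"
    return None
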