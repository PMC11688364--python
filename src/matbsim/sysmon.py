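"""System-monitoring task: a discrete visual-vigilance task.

Four round lights map positionally to four joystick buttons.  A scheduled
event turns one light on; the operator must press the matching button
before the experimenter-set timeout.  Performance is scored on reaction
time, ``(timeout - RT) / timeout * 100``, and on button-press accuracy
(wrong-button presses count as errors; expired lights count as misses
scoring 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = ["SysmonEventRecord", "SysmonState", "sysmon_score",
           "sysmon_activate", "sysmon_press", "sysmon_expire"]


@dataclass
class SysmonEventRecord:
    light: int            # 1-based light index
    onset: float
    rt: Optional[float]   # None on a miss
    outcome: str          # "hit" | "miss"
    score: float


@dataclass
class SysmonState:
    n_lights: int = 4
    timeout: float = 5.0
    light_onset: list[Optional[float]] = field(default=None)  # type: ignore[assignment]
    records: list[SysmonEventRecord] = field(default_factory=list)
    false_presses: int = 0

    def __post_init__(self) -> None:
        if self.light_onset is None:
            self.light_onset = [None] * self.n_lights

    @property
    def active_lights(self) -> list[int]:
        """1-based indices of lights currently on."""
        return [i + 1 for i, onset in enumerate(self.light_onset) if onset is not None]

    @property
    def hits(self) -> int:
        return sum(1 for r in self.records if r.outcome == "hit")

    @property
    def misses(self) -> int:
        return sum(1 for r in self.records if r.outcome == "miss")

    def accuracy(self) -> Optional[float]:
        """Percentage of presses/events answered correctly; None before any."""
        total = len(self.records) + self.false_presses
        if total == 0:
            return None
        return 100.0 * self.hits / total


def sysmon_score(rt: float, timeout: float) -> float:
    """Normalized reaction-time score: ``(timeout - rt) / timeout * 100``.

    100 for an instantaneous response, 0 at the timeout; strictly
    decreasing in ``rt``.
    """
    if timeout <= 0:
        raise ValueError("timeout must be positive")
    if rt < 0 or rt > timeout:
        raise ValueError(f"rt {rt} outside [0, timeout={timeout}]")
    return (timeout - rt) / timeout * 100.0


def sysmon_activate(state: SysmonState, light: int, t: float) -> None:
    """Turn a light on (scheduled event).  ``light`` is 1-based."""
    if not 1 <= light <= state.n_lights:
        raise ValueError(f"light {light} outside 1..{state.n_lights}")
    state.light_onset[light - 1] = t


def sysmon_press(state: SysmonState, button: int, t: float) -> Optional[SysmonEventRecord]:
    """Apply one button press at time ``t``.

    A press matching an active light turns it off and records a hit with
    its reaction time; any other press is a false press counted against
    accuracy and leaves the lights untouched.  Returns the completed
    record for a hit, else None.
    """
    if not 1 <= button <= state.n_lights:
        raise ValueError(f"button {button} outside 1..{state.n_lights}")
    onset = state.light_onset[button - 1]
    if onset is None:
        state.false_presses += 1
        return None
    rt = min(t - onset, state.timeout)
    rec = SysmonEventRecord(light=button, onset=onset, rt=rt, outcome="hit",
                            score=sysmon_score(rt, state.timeout))
    state.light_onset[button - 1] = None
    state.records.append(rec)
    return rec


def sysmon_expire(state: SysmonState, t: float) -> list[SysmonEventRecord]:
    """Expire every light whose age reached the timeout; each is a miss."""
    expired: list[SysmonEventRecord] = []
    for i, onset in enumerate(state.light_onset):
        if onset is not None and t - onset >= state.timeout:
            rec = SysmonEventRecord(light=i + 1, onset=onset, rt=None,
                                    outcome="miss", score=0.0)
            state.light_onset[i] = None
            state.records.append(rec)
            expired.append(rec)
    return expired
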