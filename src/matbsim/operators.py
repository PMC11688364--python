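"""Synthetic operators that close the simulation loop headlessly.

These models stand in for human subjects so the whole battery can be
exercised end-to-end without hardware or a GUI.  They observe only what a
human would see on screen (the :class:`ObservableState` contract — no
access to the schedule's future) and emit the same input channels a human
would use: joystick buttons, mouse entries for the communications panel, a
continuous joystick vector, pump toggles, workload ratings and automation
switches.

Three models are provided:

* :class:`NullOperator` — never responds; every discrete event becomes a
  miss (the performance floor).
* :class:`PerfectOperator` — instant, always-correct responses and a
  deviation-cancelling control law (the performance ceiling).
* :class:`StochasticOperator` — lognormal response latencies, probabilistic
  button/selection accuracy, a noisy proportional tracking control law, a
  banded pump-management heuristic and a workload rating that rises
  linearly with the concurrent discrete task load.

They are deliberately simple behavioural stand-ins, not cognitive models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from ._rng import child_rng

__all__ = ["OperatorInputs", "ObservableState", "Operator", "NullOperator",
           "PerfectOperator", "StochasticOperator", "StochasticOperatorParams",
           "operator_from_spec"]

AUTOMATED_TASKS = ("sysmon", "comms", "tracking", "resman")


@dataclass
class OperatorInputs:
    """Everything an operator can do within one simulation step."""

    sysmon_presses: list[int] = field(default_factory=list)
    comms_radio: Optional[str] = None
    comms_channel: Optional[int] = None
    comms_frequency: Optional[int] = None
    control: Optional[np.ndarray] = None
    pump_toggles: list[int] = field(default_factory=list)
    workload_rating: Optional[int] = None
    automation_toggles: list[tuple[str, bool]] = field(default_factory=list)


@dataclass
class ObservableState:
    """Operator-visible snapshot of the battery, mirroring the display.

    Contains no schedule futures and no internal engine state — test
    agents cannot exploit anything a human could not see or hear.
    """

    t: float
    dt: float
    sysmon_lights: list[bool]
    comms_event: Optional[dict]          # heard stimulus content, None if quiet
    tracking_position: np.ndarray
    tracking_target: np.ndarray
    tracking_gain: float
    tank_levels: dict[str, float]
    tank_target: float
    rm_range: float
    pumps: dict[int, dict]               # id -> {source, destination, rate, on, failed}
    workload_open: bool
    discrete_load: int
    cues: dict[str, bool]
    automation_enabled: dict[str, bool]
    automation_forced: dict[str, bool]


class Operator:
    """Base operator: does nothing.  Subclasses override :meth:`act`."""

    seed: int = 0

    def act(self, obs: ObservableState) -> OperatorInputs:
        return OperatorInputs()


class NullOperator(Operator):
    """Produces no input ever: the lower performance bound."""


def _banded_pump_policy(obs: ObservableState, band_units: float) -> list[int]:
    """Toggle pumps so main tanks move toward target once outside the band.

    Shared by the perfect operator and the heuristic strategy of the
    stochastic operator; the band width is what varies.
    """
    main = ("A", "B")
    limited = ("C", "D")
    desired_on: set[int] = set()
    for pid, p in obs.pumps.items():
        src, dst = p["source"], p["destination"]
        if dst in main and src not in main:
            if obs.tank_levels[dst] < obs.tank_target - band_units:
                desired_on.add(pid)
        elif src in main and dst in main:
            if (obs.tank_levels[src] > obs.tank_target + band_units
                    and obs.tank_levels[dst] < obs.tank_target - band_units):
                desired_on.add(pid)
        elif dst in limited:
            if obs.tank_levels[dst] < 1500.0:
                desired_on.add(pid)
    toggles = []
    for pid, p in obs.pumps.items():
        if p["failed"]:
            continue
        if p["on"] != (pid in desired_on):
            toggles.append(pid)
    return toggles


class PerfectOperator(Operator):
    """Zero-latency, always-correct operator: the performance ceiling."""

    def act(self, obs: ObservableState) -> OperatorInputs:
        inputs = OperatorInputs()
        inputs.sysmon_presses = [i + 1 for i, on in enumerate(obs.sysmon_lights) if on]
        ev = obs.comms_event
        if ev is not None and ev.get("is_own") and not ev.get("answered"):
            inputs.comms_radio = ev["radio"]
            inputs.comms_channel = ev["channel"]
            inputs.comms_frequency = ev["frequency"]
        error = obs.tracking_target - obs.tracking_position
        inputs.control = np.clip(error / (obs.tracking_gain * obs.dt), -1.0, 1.0)
        inputs.pump_toggles = _banded_pump_policy(obs, band_units=50.0)
        if obs.workload_open:
            inputs.workload_rating = int(np.clip(1 + obs.discrete_load, 1, 10))
        return inputs


class StochasticOperatorParams(BaseModel):
    """Behavioural parameters of the stochastic operator."""

    model_config = ConfigDict(extra="forbid")

    sysmon_latency_mean: float = Field(1.5, gt=0, description="s")
    sysmon_latency_cv: float = Field(0.4, ge=0)
    sysmon_accuracy: float = Field(0.95, ge=0, le=1)
    comms_latency_mean: float = Field(6.0, gt=0, description="s from stimulus onset")
    comms_latency_cv: float = Field(0.3, ge=0)
    comms_element_accuracy: float = Field(0.95, ge=0, le=1)
    distractor_response_rate: float = Field(0.05, ge=0, le=1)
    tracking_kp: float = Field(2.0, gt=0, description="1/s proportional gain")
    tracking_noise: float = Field(0.05, ge=0, description="control-units noise sd")
    rm_band: float = Field(300.0, gt=0, description="fuel-unit tolerance band")
    rm_check_interval: float = Field(2.0, gt=0, description="s between pump checks")
    workload_latency_mean: float = Field(2.0, gt=0)
    automation_policy: str = Field("never", pattern="^(never|on-cue|always)$")


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv <= 0:
        return mean
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


class StochasticOperator(Operator):
    """Human-like operator with latency, accuracy and control noise."""

    def __init__(self, params: StochasticOperatorParams | None = None, seed: int = 0):
        self.params = params or StochasticOperatorParams()
        self.seed = seed
        self.rng = child_rng(seed, "operator")
        self._light_plans: dict[int, tuple[float, int]] = {}   # light -> (when, button)
        self._prev_lights: list[bool] = []
        self._comms_plan: Optional[tuple[float, str, int, int]] = None
        self._comms_seen: Optional[float] = None
        self._workload_plan: Optional[tuple[float, int]] = None
        self._workload_seen = False
        self._next_rm_check = 0.0
        self._automation_requested = False

    def act(self, obs: ObservableState) -> OperatorInputs:
        p, rng = self.params, self.rng
        inputs = OperatorInputs()

        # -- system monitoring: plan a response when a light comes on
        if not self._prev_lights:
            self._prev_lights = [False] * len(obs.sysmon_lights)
        for i, on in enumerate(obs.sysmon_lights):
            light = i + 1
            if on and not self._prev_lights[i] and light not in self._light_plans:
                latency = _lognormal(rng, p.sysmon_latency_mean, p.sysmon_latency_cv)
                if rng.uniform() < p.sysmon_accuracy:
                    button = light
                else:
                    others = [b for b in range(1, len(obs.sysmon_lights) + 1) if b != light]
                    button = int(rng.choice(others))
                self._light_plans[light] = (obs.t + latency, button)
            if not on and light in self._light_plans:
                del self._light_plans[light]   # expired or answered; drop the plan
        for light, (when, button) in list(self._light_plans.items()):
            if obs.t >= when:
                inputs.sysmon_presses.append(button)
                del self._light_plans[light]
        self._prev_lights = [bool(x) for x in obs.sysmon_lights]

        # -- communications: one-shot entry after a lognormal latency
        ev = obs.comms_event
        if ev is None:
            self._comms_seen = None
            self._comms_plan = None
        elif not ev.get("noise") and self._comms_seen != ev["onset"]:
            self._comms_seen = ev["onset"]
            respond = (ev["is_own"] or rng.uniform() < p.distractor_response_rate)
            if respond:
                latency = _lognormal(rng, p.comms_latency_mean, p.comms_latency_cv)

                def maybe(correct, wrong_draw):
                    return correct if rng.uniform() < p.comms_element_accuracy else wrong_draw()

                radio = maybe(ev["radio"], lambda: str(rng.choice(
                    [r for r in ("NAV1", "NAV2", "COM1", "COM2") if r != ev["radio"]])))
                channel = maybe(ev["channel"], lambda: int(rng.integers(100, 1000)))
                freq = maybe(ev["frequency"], lambda: int(rng.integers(0, 1000)))
                self._comms_plan = (ev["onset"] + latency, radio, channel, freq)
        if self._comms_plan is not None and obs.t >= self._comms_plan[0]:
            _, inputs.comms_radio, inputs.comms_channel, inputs.comms_frequency = self._comms_plan
            self._comms_plan = None

        # -- tracking: noisy proportional control toward the target
        error = obs.tracking_target - obs.tracking_position
        desired_velocity = p.tracking_kp * error
        control = desired_velocity / obs.tracking_gain
        control = control + rng.normal(0.0, p.tracking_noise, size=2)
        inputs.control = np.clip(control, -1.0, 1.0)

        # -- resource management: periodic banded pump checks
        if obs.t >= self._next_rm_check:
            inputs.pump_toggles = _banded_pump_policy(obs, band_units=p.rm_band)
            self._next_rm_check = obs.t + p.rm_check_interval

        # -- workload probe: rating rises with concurrent discrete load
        if obs.workload_open and not self._workload_seen:
            self._workload_seen = True
            latency = _lognormal(rng, p.workload_latency_mean, 0.3)
            value = int(np.clip(round(1 + 1.5 * obs.discrete_load + rng.normal(0, 0.5)), 1, 10))
            self._workload_plan = (obs.t + latency, value)
        if not obs.workload_open:
            self._workload_seen = False
            if self._workload_plan is not None:
                self._workload_plan = None   # window closed before we answered
        if self._workload_plan is not None and obs.t >= self._workload_plan[0]:
            inputs.workload_rating = self._workload_plan[1]
            self._workload_plan = None

        # -- automation use policy
        if p.automation_policy == "always" and not self._automation_requested:
            inputs.automation_toggles = [(task, True) for task in AUTOMATED_TASKS]
            self._automation_requested = True
        elif p.automation_policy == "on-cue":
            for task, cue in obs.cues.items():
                if cue and not obs.automation_enabled[task]:
                    inputs.automation_toggles.append((task, True))
        return inputs


def operator_from_spec(spec: dict) -> Operator:
    """Build an operator from a parsed spec mapping (YAML dialect).

    ``{"type": "null"|"perfect"|"stochastic", "seed": int, "params": {...}}``
    """
    kind = spec.get("type", "stochastic")
    seed = int(spec.get("seed", 0))
    if kind == "null":
        return NullOperator()
    if kind == "perfect":
        return PerfectOperator()
    if kind == "stochastic":
        params = StochasticOperatorParams.model_validate(spec.get("params", {}))
        return StochasticOperator(params, seed=seed)
    raise ValueError(f"unknown operator type {kind!r}")
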