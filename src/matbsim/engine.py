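"""Fixed-timestep simulation loop coordinating every subsystem.

One engine tick advances simulated time by ``tick_dt`` (default 0.05 s,
matching the ~20 Hz loop of the desktop battery) and performs, in a fixed
documented order:

1. activate scheduled events that have come due (lights, calls, pump
   failures/shutoffs, workload prompts, automation epochs, section
   boundaries);
2. apply the operator's inputs;
3. apply the automation agents' inputs;
4. physics and timeouts — tracking control + drift, fuel flows and
   drains, light/call/probe expiry;
5. scoring — per-tick continuous scores and per-event completions, fed
   into the automation performance windows;
6. cue and forced-handoff evaluation;
7. logging of the per-tick sample row and any markers.

The fixed order is what makes a session a pure function of its seeds:
identical (config, master seed, operator seed) produce byte-identical
logs.  Simulated time is decoupled from wall clock; an optional real-time
pacing flag sleeps the loop to ~1x speed but never changes the results.
"""

from __future__ import annotations

import time
from typing import Optional

import numpy as np

from . import automation as auto_mod
from . import comms as comms_mod
from . import resman as resman_mod
from . import sysmon as sysmon_mod
from . import tracking as tracking_mod
from . import workload as workload_mod
from ._rng import child_rng
from .automation import TaskAutomation
from .comms import CommEvent, CommsTaskState, evaluate_response
from .config import SimulationConfig
from .operators import ObservableState, Operator, OperatorInputs
from .output import COLUMNS, SessionLog
from .schedule import EventSchedule, generate_schedule

__all__ = ["Engine", "run", "MARKER_LABELS"]

_EPS = 1e-9

#: Closed marker vocabulary (task placeholders expand to the four task names).
MARKER_LABELS = (
    ["Start", "Stop", "COM", "SYSMON", "RM_FAILURE", "RM_SHUTOFF",
     "WORKLOAD", "SECTION"]
    + [f"{prefix}_{task.upper()}{suffix}"
       for task in ("sysmon", "comms", "tracking", "resman")
       for prefix, suffix in (("AUTO", "_ON"), ("AUTO", "_OFF"),
                              ("CUE", "_ON"), ("CUE", "_OFF"),
                              ("FORCED", "_ON"), ("FORCED", "_RELEASED"),
                              ("TOGGLE_REJECTED", ""))]
)


class Engine:
    """Stateful simulation engine; one instance runs one session."""

    def __init__(self, config: SimulationConfig, operator: Operator,
                 schedule: Optional[EventSchedule] = None, sinks=None):
        self.config = config
        self.operator = operator
        self.schedule = schedule if schedule is not None else generate_schedule(config)
        self.sinks = list(sinks) if sinks else []
        self.tick_index = 0
        self._cursor = 0
        self._boundary_cursor = 0
        self._events = sorted(self.schedule.events, key=lambda e: e.onset)
        self._drift_rng = child_rng(config.master_seed, "tracking.drift")

        self.sysmon = sysmon_mod.SysmonState(n_lights=config.sysmon.n_lights,
                                             timeout=config.sysmon.timeout)
        self.comms = CommsTaskState()
        tc = config.tracking
        self.tracking = tracking_mod.TrackingState(
            range=tc.range, speed_level=tc.speed_level, bound=tc.range)
        self.resman = resman_mod.build_resman_state(config.resman)
        self.workload = workload_mod.WorkloadProbeState(
            interval=config.workload.interval, window=config.workload.window)
        self.autos = {task: TaskAutomation.from_config(task, config.automation.for_task(task))
                      for task in ("sysmon", "comms", "tracking", "resman")}

        self.markers: list[tuple[float, str]] = []
        self._rows: dict[str, list] = {c: [] for c in COLUMNS}
        self._active_failures: list[float] = []   # expiry times of pump failures

    # ------------------------------------------------------------------
    @property
    def sim_time(self) -> float:
        return self.tick_index * self.config.tick_dt

    def _mark(self, t: float, label: str) -> None:
        self.markers.append((t, label))
        for sink in self.sinks:
            sink.push(t, "marker", label)

    # -- stage 1: scheduled events -------------------------------------
    def _activate_due(self, t: float) -> None:
        while (self._boundary_cursor < len(self.schedule.section_boundaries)
               and self.schedule.section_boundaries[self._boundary_cursor] <= t + _EPS):
            self._mark(self.schedule.section_boundaries[self._boundary_cursor], "SECTION")
            self._boundary_cursor += 1
        while self._cursor < len(self._events) and self._events[self._cursor].onset <= t + _EPS:
            ev = self._events[self._cursor]
            self._cursor += 1
            if ev.task == "sysmon":
                sysmon_mod.sysmon_activate(self.sysmon, ev.payload["light"], t)
                self._mark(t, "SYSMON")
            elif ev.task == "comms":
                self._activate_comms(ev.payload, t)
            elif ev.task == "resman":
                kind = ev.payload["kind"]
                resman_mod.fail_pump(self.resman, ev.payload["pump"], kind, t,
                                     ev.payload.get("duration", 0.0) or 0.0)
                if kind == "failure":
                    self._active_failures.append(t + ev.payload["duration"])
                self._mark(t, "RM_FAILURE" if kind == "failure" else "RM_SHUTOFF")
            elif ev.task == "workload":
                workload_mod.probe_prompt(self.workload, t)
                self._mark(t, "WORKLOAD")
            elif ev.task == "automation":
                self._apply_automation_event(ev.payload, t)

    def _activate_comms(self, payload: dict, t: float) -> None:
        if self.comms.active is not None:
            self._close_comms(t)   # defensive; separation normally prevents this
        cc = self.config.comms
        if payload.get("noise"):
            event = CommEvent(callsign="", is_own=False, radio="COM1", channel=0,
                              frequency=0, onset=t, stimulus_duration=cc.stimulus_duration,
                              timeout=cc.timeout, is_noise=True)
        else:
            event = CommEvent(callsign=payload["callsign"], is_own=payload["is_own"],
                              radio=payload["radio"], channel=payload["channel"],
                              frequency=payload["frequency"], onset=t,
                              stimulus_duration=cc.stimulus_duration, timeout=cc.timeout)
        self.comms.active = event
        self.comms.response = comms_mod.CommResponse()
        self._mark(t, "COM")

    def _apply_automation_event(self, payload: dict, t: float) -> None:
        task = payload["task"]
        auto = self.autos[task]
        action = payload["action"]
        if action == "enable":
            if not auto.enabled:
                auto.enabled = True
                self._mark(t, f"AUTO_{task.upper()}_ON")
        elif action == "reliability":
            auto.reliability = payload["reliability"]
        elif action == "forced":
            auto.force(t, payload.get("duration"))
            self._mark(t, f"FORCED_{task.upper()}_ON")

    # -- stages 2 & 3: inputs ------------------------------------------
    def observable_state(self, t: float) -> ObservableState:
        ev = self.comms.active
        comms_view = None
        if ev is not None:
            comms_view = {"onset": ev.onset, "is_own": ev.is_own, "radio": ev.radio,
                          "channel": ev.channel, "frequency": ev.frequency,
                          "noise": ev.is_noise, "answered": self.comms.response.complete()}
        pumps = {p.id: {"source": p.source, "destination": p.destination,
                        "rate": p.flow_rate, "on": p.on, "failed": p.failed(t)}
                 for p in self.resman.pumps.values()}
        return ObservableState(
            t=t, dt=self.config.tick_dt,
            sysmon_lights=[onset is not None for onset in self.sysmon.light_onset],
            comms_event=comms_view,
            tracking_position=self.tracking.position.copy(),
            tracking_target=self.tracking.target.copy(),
            tracking_gain=self.config.tracking.gain,
            tank_levels={n: tk.level for n, tk in self.resman.tanks.items()},
            tank_target=self.resman.target_level,
            rm_range=self.resman.range,
            pumps=pumps,
            workload_open=self.workload.open_prompt is not None,
            discrete_load=self._discrete_load(t)[-1],
            cues={task: a.cue_active for task, a in self.autos.items()},
            automation_enabled={task: a.enabled for task, a in self.autos.items()},
            automation_forced={task: a.forced for task, a in self.autos.items()},
        )

    def _apply_comms_entries(self, radio, channel, frequency, t: float) -> None:
        if self.comms.active is None:
            if any(v is not None for v in (radio, channel, frequency)):
                self.comms.late_responses += 1
            return
        resp = self.comms.response
        if radio is not None:
            resp.radio = radio
        if channel is not None:
            resp.channel = channel
        if frequency is not None:
            resp.frequency = frequency
        if resp.complete() and resp.completed_at is None:
            resp.completed_at = t
        ev = self.comms.active
        if (ev.is_own and resp.radio == ev.radio and resp.channel == ev.channel
                and resp.frequency == ev.frequency):
            self._close_comms(t)   # correct response turns the active light off

    def _close_comms(self, t: float) -> None:
        rec = evaluate_response(self.comms.active, self.comms.response,
                                self.config.comms.rt_reference)
        self.comms.records.append(rec)
        if rec.outcome == "distractor_response":
            self.comms.distractor_errors += 1
        self.comms.active = None
        self.comms.response = comms_mod.CommResponse()

    def _apply_inputs(self, inputs: OperatorInputs, t: float) -> None:
        for button in inputs.sysmon_presses:
            sysmon_mod.sysmon_press(self.sysmon, button, t)
        self._apply_comms_entries(inputs.comms_radio, inputs.comms_channel,
                                  inputs.comms_frequency, t)
        for pid in inputs.pump_toggles:
            resman_mod.toggle_pump(self.resman, pid, t)
        if inputs.workload_rating is not None:
            workload_mod.probe_respond(self.workload, inputs.workload_rating, t)
        for task, desired in inputs.automation_toggles:
            auto = self.autos[task]
            if auto.enabled == desired:
                continue
            if auto.request_toggle(desired, t):
                self._mark(t, f"AUTO_{task.upper()}_{'ON' if desired else 'OFF'}")
            else:
                self._mark(t, f"TOGGLE_REJECTED_{task.upper()}")

    def _apply_automation(self, t: float) -> Optional[np.ndarray]:
        for button in auto_mod.auto_sysmon(self.autos["sysmon"], self.sysmon, t):
            sysmon_mod.sysmon_press(self.sysmon, button, t)
        response = auto_mod.auto_comms(self.autos["comms"], self.comms, t)
        if response is not None:
            self._apply_comms_entries(response.radio, response.channel,
                                      response.frequency, t)
        for pid in auto_mod.auto_resman(self.autos["resman"], self.resman, t):
            resman_mod.toggle_pump(self.resman, pid, t)
        return auto_mod.auto_tracking(self.autos["tracking"], self.tracking,
                                      self.config.tick_dt, self.config.tracking.gain)

    # -- stage 4: physics ----------------------------------------------
    def _physics(self, control: Optional[np.ndarray], t: float) -> None:
        cfg = self.config
        tracking_mod.apply_control(
            self.tracking, control if control is not None else np.zeros(2),
            cfg.tick_dt, cfg.tracking.gain, cfg.tracking.invert_x,
            cfg.tracking.invert_y, cfg.tracking.orientation)
        tracking_mod.drift_update(self.tracking, cfg.tick_dt, self._drift_rng)
        resman_mod.apply_flows(self.resman, cfg.tick_dt, t)
        sysmon_mod.sysmon_expire(self.sysmon, t)
        if self.comms.active is not None and t >= self.comms.active.window_end - _EPS:
            self._close_comms(t)
        workload_mod.probe_expire(self.workload, t)

    # ------------------------------------------------------------------
    def _discrete_load(self, t: float) -> tuple[int, int, int, int, int]:
        self._active_failures = [e for e in self._active_failures if e > t]
        n_sys = len(self.sysmon.active_lights)
        n_com = int(self.comms.active is not None and not self.comms.active.is_noise)
        n_wl = int(self.workload.open_prompt is not None)
        n_rm = len(self._active_failures)
        return n_sys, n_com, n_wl, n_rm, n_sys + n_com + n_wl + n_rm

    def step(self, inputs: Optional[OperatorInputs] = None) -> None:
        """Advance exactly one tick.  ``inputs`` defaults to operator.act()."""
        t = self.sim_time
        if self.tick_index == 0:
            self._mark(0.0, "Start")
        n_sys_before = len(self.sysmon.records)
        n_com_before = len(self.comms.records)
        n_wl_before = len(self.workload.responses)

        self._activate_due(t)
        if inputs is None:
            inputs = self.operator.act(self.observable_state(t))
        self._apply_inputs(inputs, t)
        control = self._apply_automation(t)
        if control is None:
            control = inputs.control
        self._physics(control, t)
        row = self._score(t, n_sys_before, n_com_before, n_wl_before)
        for task, auto in self.autos.items():
            flip = auto_mod.cue_update(auto, t)
            if flip is not None:
                self._mark(t, f"CUE_{task.upper()}_{'ON' if flip else 'OFF'}")
            transition = auto_mod.forced_handoff_update(auto, t)
            if transition == "forced":
                self._mark(t, f"FORCED_{task.upper()}_ON")
            elif transition == "released":
                self._mark(t, f"FORCED_{task.upper()}_RELEASED")
        self._log_row(row, t)
        self.tick_index += 1

    def _score(self, t: float, n_sys: int, n_com: int, n_wl: int) -> dict:
        """Stage 5: evaluate scores, feed automation windows, stage the row."""
        rows: dict[str, list] = {c: [] for c in COLUMNS}
        rows["time"].append(t)
        rows["tick"].append(self.tick_index)

        sys_new = self.sysmon.records[n_sys:]
        for rec in sys_new:
            self.autos["sysmon"].record_performance(t, rec.score)
        rows["sysmon_rt"].append(sys_new[-1].rt if sys_new and sys_new[-1].rt is not None
                                 else np.nan)
        rows["sysmon_score"].append(sys_new[-1].score if sys_new else np.nan)
        acc = self.sysmon.accuracy()
        rows["sysmon_accuracy"].append(np.nan if acc is None else acc)

        com_new = [r for r in self.comms.records[n_com:]
                   if not r.outcome.startswith("distractor")]
        for rec in com_new:
            self.autos["comms"].record_performance(t, rec.score)
        rows["comms_rt"].append(com_new[-1].rt if com_new and com_new[-1].rt is not None
                                else np.nan)
        rows["comms_score"].append(com_new[-1].score if com_new else np.nan)
        cacc = self.comms.accuracy()
        rows["comms_accuracy"].append(np.nan if cacc is None else cacc)

        dev = tracking_mod.deviation(self.tracking)
        dev_score, perf = tracking_mod.tracking_scores(dev, self.tracking.range)
        self.autos["tracking"].record_performance(t, perf)
        rows["tracking_deviation"].append(dev)
        rows["tracking_score"].append(dev_score)
        rows["tracking_performance"].append(perf)

        s1 = resman_mod.resman_score(self.resman.tanks["A"].level,
                                     self.resman.target_level, self.resman.range)
        s2 = resman_mod.resman_score(self.resman.tanks["B"].level,
                                     self.resman.target_level, self.resman.range)
        self.autos["resman"].record_performance(t, 100.0 - (abs(s1) + abs(s2)) / 2.0)
        rows["rm_tank1_value"].append(self.resman.tanks["A"].level)
        rows["rm_tank1_score"].append(s1)
        rows["rm_tank2_value"].append(self.resman.tanks["B"].level)
        rows["rm_tank2_score"].append(s2)

        wl_new = self.workload.responses[n_wl:]
        answered = [r for r in wl_new if r.value is not None]
        rows["workload_value"].append(answered[-1].value if answered else np.nan)
        rows["workload_rt"].append(answered[-1].rt if answered else np.nan)

        n_sysload, n_comload, n_wlload, n_rmload, total = self._discrete_load(t)
        rows["load_sysmon"].append(n_sysload)
        rows["load_comms"].append(n_comload)
        rows["load_workload"].append(n_wlload)
        rows["load_resman"].append(n_rmload)
        rows["load_total"].append(total)
        return rows

    def _log_row(self, row: dict, t: float) -> None:
        """Stage 7: append the sample row (automation state read post-handoff)."""
        for task in ("sysmon", "comms", "tracking", "resman"):
            row[f"auto_{task}"].append(int(self.autos[task].enabled))
        for col, values in row.items():
            self._rows[col].extend(values)
        for sink in self.sinks:
            sink.push(t, "tracking_score", row["tracking_score"][0])
            sink.push(t, "rm_tank1_score", row["rm_tank1_score"][0])
            sink.push(t, "rm_tank2_score", row["rm_tank2_score"][0])

    def run(self) -> SessionLog:
        """Run the full session and assemble the log."""
        n_ticks = self.config.n_ticks
        wall_start = time.perf_counter()
        for _ in range(n_ticks):
            if self.config.realtime:
                target = wall_start + self.sim_time
                lag = target - time.perf_counter()
                if lag > 0:
                    time.sleep(lag)
            self.step()
        wall = time.perf_counter() - wall_start
        self._mark(self.config.duration, "Stop")
        return SessionLog.assemble(
            rows=self._rows, markers=self.markers,
            section_boundaries=list(self.schedule.section_boundaries),
            meta={"mean_tick_duration": wall / max(n_ticks, 1),
                  "tick_dt": self.config.tick_dt,
                  "duration": self.config.duration,
                  "master_seed": self.config.master_seed,
                  "operator_seed": getattr(self.operator, "seed", None),
                  "n_ticks": n_ticks})


def run(config: SimulationConfig, operator: Operator,
        schedule: Optional[EventSchedule] = None, sinks=None) -> SessionLog:
    """Run one session: a pure function of (config, seeds, operator seed)."""
    return Engine(config, operator, schedule=schedule, sinks=sinks).run()
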