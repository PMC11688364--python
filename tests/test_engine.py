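import numpy as np
import pytest

from matbsim import (Engine, NullOperator, PerfectOperator, SimulationConfig,
                     generate_schedule, run)
from matbsim.engine import MARKER_LABELS
from matbsim.operators import OperatorInputs
from matbsim.schedule import EventSchedule, ScheduledEvent


def test_null_step_advances_only_time(quiet_config):
    engine = Engine(quiet_config, NullOperator())
    engine.step(OperatorInputs())
    assert engine.tick_index == 1
    assert engine.sim_time == pytest.approx(0.05)
    df_row = {c: v[0] for c, v in engine._rows.items()}
    assert df_row["tracking_deviation"] == 0.0
    assert df_row["rm_tank1_score"] == 0.0
    assert np.isnan(df_row["sysmon_score"])


def test_due_event_activates_within_step(quiet_config):
    schedule = EventSchedule(
        events=[ScheduledEvent(0.12, "sysmon", {"light": 3})],
        seed=0, duration=quiet_config.duration)
    engine = Engine(quiet_config, NullOperator(), schedule=schedule)
    engine.step(OperatorInputs())   # t=0
    engine.step(OperatorInputs())   # t=0.05
    assert engine.sysmon.active_lights == []
    engine.step(OperatorInputs())   # t=0.10 — 0.12 not yet due
    assert engine.sysmon.active_lights == []
    engine.step(OperatorInputs())   # t=0.15 — onset in (0.10, 0.15]
    assert engine.sysmon.active_lights == [3]


def test_tick_count_matches_duration_over_dt(null_session_300):
    config, log = null_session_300
    assert len(log.samples) == 6000            # 300 s at 0.05 s
    assert log.samples["tick"].iloc[-1] == 5999   # 0-based tick index
    assert log.samples["time"].iloc[-1] == pytest.approx(300.0 - 0.05)


def test_run_is_deterministic_byte_identical(base_config):
    a = run(base_config, NullOperator())
    b = run(base_config, NullOperator())
    assert a.equivalent(b)
    assert a.samples.to_csv(index=False) == b.samples.to_csv(index=False)


def test_start_and_stop_markers_bracket_session(null_session_300):
    _, log = null_session_300
    labels = log.markers["label"].tolist()
    assert labels[0] == "Start" and labels[-1] == "Stop"
    assert log.markers["time"].iloc[0] == 0.0
    assert log.markers["time"].iloc[-1] == 300.0
    assert log.markers["time"].is_monotonic_increasing
    assert set(labels) <= set(MARKER_LABELS)


def test_perfect_operator_scores_ceiling(base_config):
    log = run(base_config, PerfectOperator())
    assert np.nanmean(log.samples["sysmon_score"]) == pytest.approx(100.0)


def test_discrete_task_loading_matches_brute_force_recount(null_session_300):
    """Oracle: recount concurrently active discrete events at every tick
    from the schedule and the null operator's guaranteed non-response."""
    config, log = null_session_300
    schedule = generate_schedule(config)
    times = log.samples["time"].to_numpy()

    def active_count(task, length, times):
        onsets = np.array([e.onset for e in schedule.for_task(task)])
        # activation snaps to the next tick boundary
        dt = config.tick_dt
        snapped = np.ceil(onsets / dt - 1e-9) * dt
        counts = np.zeros(len(times))
        for s in snapped:
            counts += (times >= s - 1e-9) & (times < s + length - 1e-9)
        return counts

    expected_sys = active_count("sysmon", config.sysmon.timeout, times)
    assert np.array_equal(log.samples["load_sysmon"].to_numpy(float), expected_sys)
    expected_com = active_count("comms", config.comms.total_window, times)
    assert np.array_equal(log.samples["load_comms"].to_numpy(float), expected_com)
    total = (log.samples["load_sysmon"] + log.samples["load_comms"]
             + log.samples["load_workload"] + log.samples["load_resman"])
    assert np.array_equal(total.to_numpy(), log.samples["load_total"].to_numpy())


def test_automation_columns_reflect_enabled_state():
    config = SimulationConfig.model_validate({
        "duration": 60.0, "master_seed": 1,
        "demand": {"event_counts": {"sysmon": 0, "comms": 0,
                                    "resman_failures": 0, "resman_shutoffs": 0}},
        "automation": {"tracking": {"enabled": True, "reliability": 80.0}},
    })
    log = run(config, NullOperator())
    assert (log.samples["auto_tracking"] == 1).all()
    assert (log.samples["auto_sysmon"] == 0).all()


def test_forced_handoff_lockout_end_to_end():
    """A scheduled forced handoff enables automation, rejects the operator's
    toggle attempts while locked, and releases on time."""

    class Defector(NullOperator):
        def act(self, obs):
            inputs = OperatorInputs()
            if obs.automation_enabled["tracking"]:
                inputs.automation_toggles = [("tracking", False)]
            return inputs

    config = SimulationConfig.model_validate({
        "duration": 60.0, "master_seed": 1,
        "demand": {"event_counts": {"sysmon": 0, "comms": 0,
                                    "resman_failures": 0, "resman_shutoffs": 0}},
        "automation": {"tracking": {"forced_windows": [{"time": 10.0,
                                                        "duration": 20.0}]}},
    })
    log = run(config, NullOperator())
    on = log.samples.loc[log.samples["time"].between(10.0, 29.9), "auto_tracking"]
    assert (on == 1).all()
    labels = log.markers["label"].tolist()
    assert "FORCED_TRACKING_ON" in labels and "FORCED_TRACKING_RELEASED" in labels

    log2 = run(config, Defector())
    during = log2.samples.loc[log2.samples["time"].between(10.0, 29.9), "auto_tracking"]
    assert (during == 1).all()                    # toggles rejected while locked
    assert "TOGGLE_REJECTED_TRACKING" in log2.markers["label"].tolist()
    after = log2.samples.loc[log2.samples["time"] > 30.1, "auto_tracking"]
    assert (after == 0).all()                     # released; operator turned it off


def test_section_markers_on_appended_schedule():
    cfg1 = SimulationConfig.model_validate({
        "duration": 60.0, "master_seed": 1,
        "demand": {"event_counts": {"sysmon": 6, "comms": 0,
                                    "resman_failures": 0, "resman_shutoffs": 0}}})
    cfg2 = SimulationConfig.model_validate({
        "duration": 60.0, "master_seed": 2,
        "demand": {"event_counts": {"sysmon": 1, "comms": 0,
                                    "resman_failures": 0, "resman_shutoffs": 0}}})
    from matbsim import append_schedule
    combined = append_schedule(generate_schedule(cfg1), cfg2)
    run_cfg = cfg1.model_copy(update={"duration": 120.0})
    log = run(run_cfg, NullOperator(), schedule=combined)
    sections = log.markers[log.markers["label"] == "SECTION"]
    assert sections["time"].tolist() == [60.0]
    first = log.samples[log.samples["time"] < 60.0]["sysmon_score"].dropna()
    second = log.samples[log.samples["time"] >= 60.0]["sysmon_score"].dropna()
    assert len(first) == 6 and len(second) == 1   # density transition visible
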