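import numpy as np
import pytest

from matbsim import NullOperator, SimulationConfig, run
from matbsim.automation import (TaskAutomation, auto_sysmon, cue_update,
                                forced_handoff_update, target_value)
from matbsim.selftest import reliability_recovery
from matbsim.sysmon import SysmonState, sysmon_activate


class TestTargetValue:
    @pytest.mark.parametrize("limit, reliability, expected", [
        (5.0, 100.0, 0.0),     # perfect automation responds instantly
        (5.0, 0.0, 5.0),       # zero reliability waits out the whole limit
        (5.0, 75.0, 1.25),     # 5 - 75*5/100
        (100.0, 50.0, 50.0),
    ])
    def test_formula(self, limit, reliability, expected):
        assert target_value(limit, reliability) == pytest.approx(expected)

    def test_out_of_range_reliability(self):
        with pytest.raises(ValueError):
            target_value(5.0, 101.0)
        with pytest.raises(ValueError):
            target_value(0.0, 50.0)


class TestSysmonAgent:
    def test_presses_exactly_when_age_reaches_target(self):
        auto = TaskAutomation("sysmon", enabled=True, reliability=75.0)
        state = SysmonState(timeout=5.0)
        sysmon_activate(state, 2, 10.0)
        assert auto_sysmon(auto, state, 11.2) == []
        assert auto_sysmon(auto, state, 11.25) == [2]   # age = 1.25 s

    def test_never_wrong_button_never_idle_action(self):
        auto = TaskAutomation("sysmon", enabled=True, reliability=50.0)
        state = SysmonState(timeout=5.0)
        assert auto_sysmon(auto, state, 100.0) == []
        sysmon_activate(state, 1, 100.0)
        sysmon_activate(state, 4, 100.0)
        assert sorted(auto_sysmon(auto, state, 102.5)) == [1, 4]

    def test_disabled_agent_does_nothing(self):
        auto = TaskAutomation("sysmon", enabled=False, reliability=100.0)
        state = SysmonState(timeout=5.0)
        sysmon_activate(state, 1, 0.0)
        assert auto_sysmon(auto, state, 4.0) == []


def test_reliability_recovery_across_levels():
    """The headline property: automated agents for system monitoring,
    communications and tracking achieve a long-run mean score equal to
    their reliability within +/-1 over a 300 s session."""
    for task, target, achieved in reliability_recovery(duration=300.0):
        assert achieved == pytest.approx(target, abs=1.0), (task, target)


def test_resman_automation_keeps_score_within_band():
    """The banded fuel controller holds |signed tank score| within the
    trigger band (100 - R) plus its hysteresis margin after a transient."""
    reliability = 60.0
    config = SimulationConfig.model_validate({
        "duration": 300.0, "master_seed": 5,
        "demand": {"event_counts": {"sysmon": 0, "comms": 0,
                                    "resman_failures": 0, "resman_shutoffs": 0}},
        "automation": {"resman": {"enabled": True, "reliability": reliability}},
    })
    log = run(config, NullOperator())
    steady = log.samples[log.samples["time"] >= 60.0]
    band = 100.0 - reliability
    hysteresis = 0.5 * band
    for col in ("rm_tank1_score", "rm_tank2_score"):
        assert np.max(np.abs(steady[col].to_numpy())) <= band + hysteresis


class TestCueing:
    def _auto(self):
        return TaskAutomation("tracking", cue_threshold=50.0, perf_window=30.0)

    def test_cue_off_while_average_above_threshold(self):
        auto = self._auto()
        auto.record_performance(1.0, 90.0)
        assert cue_update(auto, 1.0) is None
        assert not auto.cue_active

    def test_cue_turns_on_below_threshold_and_clears_on_recovery(self):
        auto = self._auto()
        auto.record_performance(1.0, 20.0)
        assert cue_update(auto, 1.0) is True
        assert auto.cue_active
        for t in (2.0, 3.0, 4.0):
            auto.record_performance(t, 100.0)
        assert cue_update(auto, 4.0) is False
        assert not auto.cue_active

    def test_cue_implies_average_below_threshold(self):
        auto = self._auto()
        for t, s in [(1, 30.0), (2, 80.0), (3, 20.0), (4, 95.0)]:
            auto.record_performance(float(t), s)
            cue_update(auto, float(t))
            if auto.cue_active:
                assert auto.moving_average() < auto.cue_threshold


class TestForcedHandoff:
    def test_time_locked_handoff_rejects_toggles_until_release(self):
        auto = TaskAutomation("sysmon")
        auto.force(120.0, duration=60.0)
        assert auto.enabled and auto.forced
        assert not auto.request_toggle(False, 130.0)
        assert auto.enabled                       # toggle rejected
        assert auto.rejected_toggles == [(130.0, False)]
        assert forced_handoff_update(auto, 179.9) is None
        assert forced_handoff_update(auto, 180.0) == "released"
        assert auto.enabled and not auto.forced   # released but still on
        assert auto.request_toggle(False, 181.0)  # operator may now disable
        assert not auto.enabled

    def test_performance_trigger_fires_below_threshold(self):
        auto = TaskAutomation("comms", forced_perf_threshold=40.0,
                              release_threshold=60.0, release_dwell=10.0)
        auto.record_performance(10.0, 20.0)
        assert forced_handoff_update(auto, 10.0) == "forced"
        assert auto.enabled and auto.forced

    def test_stabilization_release_requires_dwell(self):
        auto = TaskAutomation("comms", forced_perf_threshold=40.0,
                              release_threshold=60.0, release_dwell=10.0,
                              perf_window=30.0)
        auto.force(0.0, None)
        for t in range(1, 10):
            auto.record_performance(float(t), 80.0)
            assert forced_handoff_update(auto, float(t)) is None
        auto.record_performance(11.0, 80.0)
        assert forced_handoff_update(auto, 11.0) == "released"

    def test_dip_during_dwell_resets_the_clock(self):
        auto = TaskAutomation("comms", release_threshold=60.0, release_dwell=5.0,
                              perf_window=2.0)
        auto.force(0.0, None)
        auto.record_performance(1.0, 90.0)
        forced_handoff_update(auto, 1.0)
        auto.record_performance(3.0, 10.0)        # dip below threshold
        assert forced_handoff_update(auto, 3.0) is None
        for t in (4.0, 6.0, 8.0):
            auto.record_performance(t, 95.0)
            forced_handoff_update(auto, t)
        assert auto.forced                        # dwell clock restarted
        auto.record_performance(11.0, 95.0)
        assert forced_handoff_update(auto, 11.0) == "released"
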