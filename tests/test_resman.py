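import numpy as np
import pytest

from matbsim.config import ResmanConfig
from matbsim.resman import (apply_flows, build_resman_state, fail_pump,
                            resman_score, toggle_pump)


def _state(**overrides):
    return build_resman_state(ResmanConfig(**overrides))


def test_network_has_six_tanks_and_eight_pumps():
    state = _state()
    assert set(state.tanks) == {"A", "B", "C", "D", "E", "F"}
    assert sorted(state.pumps) == list(range(1, 9))
    assert state.tanks["A"].level == 2000.0
    assert state.tanks["C"].level == 1000.0       # limited tanks start at 1,000
    assert state.tanks["E"].infinite


class TestScore:
    @pytest.mark.parametrize("level, expected", [
        (2000.0, 0.0),        # on target
        (2500.0, 50.0),       # (2500 - 2000) / 1000 * 100
        (1000.0, -100.0),     # (1000 - 2000) / 1000 * 100
        (4000.0, 100.0),      # clamped
        (0.0, -100.0),        # clamped
    ])
    def test_signed_normalized_score(self, level, expected):
        assert resman_score(level, 2000.0, 1000.0) == pytest.approx(expected)

    def test_range_must_be_positive(self):
        with pytest.raises(ValueError):
            resman_score(2000.0, 2000.0, 0.0)


class TestToggle:
    def test_double_toggle_is_identity(self):
        state = _state()
        assert not state.pumps[1].on
        toggle_pump(state, 1, 0.0)
        assert state.pumps[1].on
        toggle_pump(state, 1, 0.0)
        assert not state.pumps[1].on

    def test_failed_pump_ignores_toggle_and_logs(self):
        state = _state()
        fail_pump(state, 3, "failure", t=10.0, duration=15.0)
        assert not toggle_pump(state, 3, 12.0)
        assert not state.pumps[3].on
        assert state.rejected_toggles == [(12.0, 3)]

    def test_shutoff_is_immediately_retoggleable(self):
        state = _state()
        toggle_pump(state, 5, 0.0)
        fail_pump(state, 5, "shutoff", t=10.0, duration=0.0)
        assert not state.pumps[5].on
        assert toggle_pump(state, 5, 10.05)
        assert state.pumps[5].on

    def test_failure_expiry_restores_toggleability(self):
        state = _state()
        fail_pump(state, 2, "failure", t=0.0, duration=15.0)
        assert not toggle_pump(state, 2, 14.9)
        assert toggle_pump(state, 2, 15.0)

    def test_unknown_pump_rejected(self):
        with pytest.raises(ValueError):
            toggle_pump(_state(), 9, 0.0)


class TestFlows:
    def test_drain_rate_over_one_second(self):
        state = _state(drain_rate=600.0)
        apply_flows(state, 1.0, 0.0)
        assert state.tanks["A"].level == pytest.approx(2000.0 - 10.0)
        assert state.tanks["B"].level == pytest.approx(2000.0 - 10.0)

    def test_pump_transfer_rate_times_dt(self):
        state = _state(drain_rate=0.0)
        toggle_pump(state, 1, 0.0)          # C -> A at 800/min
        apply_flows(state, 3.0, 0.0)
        assert state.tanks["A"].level == pytest.approx(2000.0 + 40.0)
        assert state.tanks["C"].level == pytest.approx(1000.0 - 40.0)

    def test_empty_limited_tank_supplies_nothing(self):
        state = _state(drain_rate=0.0, limited_start=0.0)
        toggle_pump(state, 1, 0.0)
        apply_flows(state, 10.0, 0.0)
        assert state.tanks["A"].level == pytest.approx(2000.0)
        assert state.tanks["C"].level == 0.0

    def test_source_fuel_split_pro_rata_when_scarce(self):
        # pumps 1 (C->A, 800/min) and a rewired C->B pump share 5 units
        state = _state(drain_rate=0.0, limited_start=5.0,
                       pump_topology=[["C", "A"], ["C", "B"], ["D", "B"], ["F", "B"],
                                      ["E", "C"], ["F", "D"], ["A", "B"], ["B", "A"]],
                       pump_flow_rates=[800.0, 800.0, 800.0, 600.0,
                                        600.0, 600.0, 400.0, 400.0])
        toggle_pump(state, 1, 0.0)
        toggle_pump(state, 2, 0.0)
        apply_flows(state, 60.0, 0.0)       # each pump wants 800, only 5 exist
        assert state.tanks["C"].level == pytest.approx(0.0)
        assert state.tanks["A"].level == pytest.approx(2002.5)
        assert state.tanks["B"].level == pytest.approx(2002.5)

    def test_destination_capacity_respected(self):
        state = _state(drain_rate=0.0, main_start=3990.0)
        toggle_pump(state, 1, 0.0)
        apply_flows(state, 60.0, 0.0)       # wants 800, headroom only 10
        assert state.tanks["A"].level == pytest.approx(4000.0)
        assert state.tanks["C"].level == pytest.approx(990.0)

    def test_closed_subsystem_conserves_total_fuel(self):
        # drains off, no pump touching the infinite tanks
        state = _state(drain_rate=0.0)
        for pid in (1, 3, 7, 8):            # C->A, D->B, A->B, B->A
            toggle_pump(state, pid, 0.0)
        total0 = sum(tk.level for tk in state.tanks.values() if not tk.infinite)
        rng = np.random.default_rng(0)
        for i in range(200):
            apply_flows(state, 0.05, i * 0.05)
            if rng.uniform() < 0.1:
                toggle_pump(state, int(rng.integers(1, 9)), i * 0.05)
        total = sum(tk.level for tk in state.tanks.values() if not tk.infinite)
        # pumps 2,4,5,6 may have been toggled on: account via the inflow meter
        assert total == pytest.approx(total0 + state.total_infinite_inflow)

    def test_fuel_ledger_balances_every_tick(self):
        # conservation oracle: change in bounded fuel equals inflow from the
        # infinite tanks minus the drained amount, tick by tick
        state = _state()
        for pid in (1, 2, 3, 4, 5, 6):
            toggle_pump(state, pid, 0.0)
        for i in range(500):
            before = sum(tk.level for tk in state.tanks.values() if not tk.infinite)
            in0, out0 = state.total_infinite_inflow, state.total_drained
            apply_flows(state, 0.05, i * 0.05)
            after = sum(tk.level for tk in state.tanks.values() if not tk.infinite)
            delta_in = state.total_infinite_inflow - in0
            delta_out = state.total_drained - out0
            assert after - before == pytest.approx(delta_in - delta_out, abs=1e-9)
            for tk in state.tanks.values():
                if not tk.infinite:
                    assert -1e-9 <= tk.level <= tk.capacity + 1e-9

    def test_failed_pump_never_transfers(self):
        state = _state(drain_rate=0.0)
        toggle_pump(state, 1, 0.0)
        fail_pump(state, 1, "failure", t=0.0, duration=15.0)
        apply_flows(state, 10.0, 5.0)
        assert state.tanks["A"].level == pytest.approx(2000.0)
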