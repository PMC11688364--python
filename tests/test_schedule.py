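import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matbsim.config import SimulationConfig
from matbsim.schedule import (CapacityError, append_schedule, export_schedule,
                              generate_schedule, import_schedule, place_events,
                              schedule_summary)


def _config(duration=300.0, seed=0, sysmon=20, comms=0, fails=0, shuts=0, **extra):
    payload = {
        "duration": duration, "master_seed": seed,
        "demand": {"event_counts": {"sysmon": sysmon, "comms": comms,
                                    "resman_failures": fails,
                                    "resman_shutoffs": shuts}},
    }
    payload.update(extra)
    return SimulationConfig.model_validate(payload)


def test_zero_demand_leaves_only_workload_prompts():
    sched = generate_schedule(_config(sysmon=0))
    tasks = {e.task for e in sched.events}
    assert tasks == {"workload"}
    assert len(sched.for_task("workload")) == 10  # floor(300/30)


def test_same_seed_gives_identical_schedules():
    a = generate_schedule(_config(sysmon=20, comms=5, fails=3, shuts=3, seed=9))
    b = generate_schedule(_config(sysmon=20, comms=5, fails=3, shuts=3, seed=9))
    assert a.events == b.events
    c = generate_schedule(_config(sysmon=20, comms=5, fails=3, shuts=3, seed=10))
    assert a.events != c.events


def test_sysmon_gaps_respect_timeout_by_exhaustive_pairwise_check():
    cfg = _config(duration=300.0, sysmon=20)
    onsets = sorted(e.onset for e in generate_schedule(cfg).for_task("sysmon"))
    assert len(onsets) == 20
    for a, b in zip(onsets, onsets[1:]):
        assert b - a >= cfg.sysmon.timeout - 1e-9
    assert onsets[-1] <= cfg.duration - cfg.sysmon.timeout + 1e-9


def test_other_tasks_do_not_perturb_a_tasks_placement():
    only_sysmon = generate_schedule(_config(sysmon=15, seed=4)).for_task("sysmon")
    with_others = generate_schedule(
        _config(sysmon=15, comms=5, fails=2, shuts=2, seed=4)).for_task("sysmon")
    assert only_sysmon == with_others


def test_infeasible_density_raises_capacity_error():
    with pytest.raises(CapacityError):
        generate_schedule(_config(duration=60.0, sysmon=20))  # 20*5s > 60s


def test_distractor_calls_are_added_on_top_of_demand():
    cfg = SimulationConfig.model_validate({
        "duration": 300.0,
        "demand": {"event_counts": {"comms": 8}},
        "comms": {"confederate_rate": 0.5},
    })
    events = generate_schedule(cfg).for_task("comms")
    own = [e for e in events if e.payload.get("is_own")]
    assert len(own) == 8
    assert len(events) == 8 + 4


def test_append_offsets_events_and_marks_boundary():
    base = generate_schedule(_config(duration=120.0, sysmon=8, seed=1))
    base_events_before = list(base.events)
    combined = append_schedule(base, _config(duration=120.0, sysmon=2, seed=2))
    assert base.events == base_events_before            # base untouched
    assert combined.section_boundaries == [120.0]
    assert combined.duration == 240.0
    first = [e for e in combined.for_task("sysmon") if e.onset < 120.0]
    second = [e for e in combined.for_task("sysmon") if e.onset >= 120.0]
    assert len(first) == 8 and len(second) == 2         # density drops


def test_append_empty_segment_adds_only_boundary_and_prompts():
    base = generate_schedule(_config(duration=120.0, sysmon=5))
    combined = append_schedule(base, _config(duration=60.0, sysmon=0))
    assert combined.section_boundaries == [120.0]
    added = [e for e in combined.events if e.onset >= 120.0]
    assert all(e.task == "workload" for e in added)


def test_two_appends_yield_ascending_boundaries():
    s = generate_schedule(_config(duration=60.0, sysmon=0))
    s = append_schedule(s, _config(duration=60.0, sysmon=0))
    s = append_schedule(s, _config(duration=60.0, sysmon=0))
    assert s.section_boundaries == [60.0, 120.0]


def test_summary_counts_and_min_gap_match_brute_force():
    cfg = _config(sysmon=12, comms=4, fails=2, shuts=2)
    sched = generate_schedule(cfg)
    summary = schedule_summary(sched)
    for task in ("sysmon", "comms", "resman", "workload"):
        onsets = sorted(e.onset for e in sched.for_task(task))
        assert summary.loc[task, "count"] == len(onsets)
        if len(onsets) > 1:
            brute = min(b - a for a, b in zip(onsets, onsets[1:]))
            assert summary.loc[task, "min_gap"] == pytest.approx(brute)
    empty = schedule_summary(generate_schedule(
        _config(sysmon=0, workload={"interval": 400.0, "window": 10.0})))
    assert (empty["count"] == 0).all()


def test_export_import_round_trip(tmp_path):
    sched = append_schedule(generate_schedule(_config(duration=120.0, sysmon=6, comms=3)),
                            _config(duration=60.0, sysmon=2))
    path = tmp_path / "sched.csv"
    export_schedule(sched, path)
    loaded = import_schedule(path)
    assert loaded.events == sched.events
    assert loaded.section_boundaries == sched.section_boundaries
    assert loaded.duration == sched.duration
    assert loaded.seed == sched.seed


@given(n=st.integers(0, 30), seed=st.integers(0, 2**20),
       sep=st.floats(0.5, 10.0), duration=st.floats(200.0, 400.0))
@settings(max_examples=60, derandomize=True)
def test_placement_respects_separation_or_raises(n, seed, sep, duration):
    rng = np.random.default_rng(seed)
    if duration - sep - (n - 1) * sep < 0 and n > 0:
        with pytest.raises(CapacityError):
            place_events(n, duration, sep, sep, rng)
        return
    onsets = place_events(n, duration, sep, sep, rng)
    assert len(onsets) == n
    assert np.all(np.diff(onsets) >= sep - 1e-9)
    if n:
        assert onsets[0] >= 0 and onsets[-1] <= duration - sep + 1e-9


def test_workload_prompts_periodic_with_final_clamped():
    sched = generate_schedule(_config(duration=300.0, sysmon=0))
    onsets = [e.onset for e in sched.for_task("workload")]
    assert onsets == [30.0, 60.0, 90.0, 120.0, 150.0, 180.0, 210.0, 240.0, 270.0, 290.0]
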