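"""Reliability-recovery self-check used by the CLI and the test suite.

For each reliability level R the automated agents for system monitoring,
communications and tracking run a full session with a null operator; the
mean achieved normalized score must come back equal to R (the tracking
agent is measured on the higher-is-better performance index after a
transient).  Resource management is excluded here because its banded
controller targets a score bound rather than an equality.
"""

from __future__ import annotations

import numpy as np

from .config import SimulationConfig
from .engine import run
from .operators import NullOperator

__all__ = ["reliability_recovery", "achieved_scores", "TRANSIENT"]

#: Seconds of tracking data discarded while the agent converges to its ring.
TRANSIENT = 30.0


def _session_config(reliability: float, duration: float, seed: int) -> SimulationConfig:
    return SimulationConfig.model_validate({
        "duration": duration,
        "master_seed": seed,
        "demand": {"event_counts": {"sysmon": 20, "comms": 10,
                                    "resman_failures": 0, "resman_shutoffs": 0}},
        "automation": {
            "sysmon": {"enabled": True, "reliability": reliability},
            "comms": {"enabled": True, "reliability": reliability},
            "tracking": {"enabled": True, "reliability": reliability},
        },
    })


def achieved_scores(reliability: float, duration: float = 300.0,
                    seed: int = 20240) -> dict[str, float]:
    """Mean achieved scores for the three equality-targeting agents."""
    log = run(_session_config(reliability, duration, seed), NullOperator())
    df = log.samples
    steady = df[df["time"] >= TRANSIENT]
    return {
        "sysmon": float(np.nanmean(df["sysmon_score"].to_numpy(float))),
        "comms": float(np.nanmean(df["comms_score"].to_numpy(float))),
        "tracking": float(np.mean(steady["tracking_performance"].to_numpy(float))),
    }


def reliability_recovery(levels=(25.0, 50.0, 75.0, 100.0),
                         duration: float = 300.0) -> list[tuple[str, float, float]]:
    """(task, target R, achieved mean score) for each task and level."""
    table = []
    for r in levels:
        achieved = achieved_scores(r, duration=duration)
        for task in ("sysmon", "comms", "tracking"):
            table.append((task, r, achieved[task]))
    return table
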