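"""Compensatory tracking: a continuous control task.

A cursor (the "circle") drifts randomly across a square grid while the
operator applies joystick input to keep it inside the central target
square.  Drift is a capped random walk on velocity whose step size scales
with the configured speed level.  Every tick the Euclidean deviation
between cursor and target is scored two ways:

* ``deviation_score`` — ``deviation / range * 100``, the logged raw-error
  percentage (increases with error);
* ``performance_score`` — ``100 - deviation_score``, the higher-is-better
  index used by reliability targeting and performance cueing, so that a
  tracking agent targeting reliability R achieves performance R.

Both are kept explicitly because the error percentage rises with poor
tracking while every other task's score rises with good performance; the
complement reconciles the two conventions and both columns are logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrackingState", "drift_update", "apply_control", "tracking_scores",
           "deviation"]

#: Velocity random-walk scale (grid units / s^1.5) and cap (grid units / s)
#: per speed level unit.  Level 0 disables drift entirely.
ACCEL_SIGMA_PER_LEVEL = 5.0
VMAX_PER_LEVEL = 10.0


@dataclass
class TrackingState:
    range: float = 100.0            # deviation scoring as 100% error
    speed_level: int = 2
    position: np.ndarray = field(default_factory=lambda: np.zeros(2))
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(2))
    target: np.ndarray = field(default_factory=lambda: np.zeros(2))
    #: grid half-width; cursor reflects at +/- this bound per axis
    bound: float = 100.0
    clipped_inputs: int = 0


def deviation(state: TrackingState) -> float:
    """Euclidean distance between cursor and target centre."""
    return float(np.linalg.norm(state.position - state.target))


def drift_update(state: TrackingState, dt: float, rng: np.random.Generator) -> None:
    """Advance the random drift by one step of ``dt`` seconds.

    The velocity receives a zero-mean Gaussian increment scaled by the
    speed level and sqrt(dt), is capped in magnitude, and the position is
    advanced and reflected at the grid edges.  Speed level 0 leaves the
    cursor untouched.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.speed_level <= 0:
        return
    sigma = ACCEL_SIGMA_PER_LEVEL * state.speed_level
    vmax = VMAX_PER_LEVEL * state.speed_level
    state.velocity = state.velocity + rng.normal(0.0, sigma * np.sqrt(dt), size=2)
    speed = np.linalg.norm(state.velocity)
    if speed > vmax:
        state.velocity *= vmax / speed
    state.position = state.position + state.velocity * dt
    _reflect(state)


def _reflect(state: TrackingState) -> None:
    for axis in range(2):
        p = state.position[axis]
        if p > state.bound:
            state.position[axis] = 2 * state.bound - p
            state.velocity[axis] *= -1.0
        elif p < -state.bound:
            state.position[axis] = -2 * state.bound - p
            state.velocity[axis] *= -1.0


def apply_control(state: TrackingState, control, dt: float, gain: float,
                  invert_x: bool = False, invert_y: bool = False,
                  orientation: str = "cursor-to-target") -> None:
    """Apply one joystick control vector in [-1,1]^2 for ``dt`` seconds.

    The moved entity shifts by ``gain * control * dt``.  In the default
    orientation the control moves the cursor; in the reversed orientation
    ("operator control of the target square") it moves the target instead —
    the deviation math is unchanged.  Out-of-range components are clipped
    and counted.
    """
    c = np.asarray(control, dtype=float).copy()
    if np.any(np.abs(c) > 1.0):
        state.clipped_inputs += 1
        c = np.clip(c, -1.0, 1.0)
    if invert_x:
        c[0] = -c[0]
    if invert_y:
        c[1] = -c[1]
    delta = gain * c * dt
    if orientation == "target-to-cursor":
        state.target = state.target + delta
    else:
        state.position = state.position + delta
    _reflect(state)


def tracking_scores(dev: float, rng_limit: float) -> tuple[float, float]:
    """(deviation_score, performance_score) for a deviation and range.

    ``deviation_score = min(dev/range, 1) * 100``;
    ``performance_score = 100 - deviation_score``.  They always sum to 100.
    """
    if rng_limit <= 0:
        raise ValueError("range must be positive")
    if dev < 0:
        raise ValueError("deviation must be non-negative")
    dev_score = min(dev / rng_limit, 1.0) * 100.0
    return dev_score, 100.0 - dev_score
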