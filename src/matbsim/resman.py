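"""Resource management: strategic fuel transfer across six tanks.

Tanks A and B are the scored main tanks; the operator must hold each at
the 2,000-unit target while both drain continuously.  Tanks C and D are
limited supply tanks starting at 1,000 units (their pumps are fast but
they cannot be refilled beyond what pumps deliver and stop supplying at
zero).  Tanks E and F hold infinite fuel (their pumps are slower).  Eight
pumps move fuel along a fixed topology; scheduled failures lock a pump off
for a period, scheduled shutoffs merely switch an active pump off.

Each main tank is scored with the signed percentage deviation
``(level - 2000) / range * 100`` clamped to [-100, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["Tank", "Pump", "ResmanState", "build_resman_state", "toggle_pump",
           "fail_pump", "apply_flows", "resman_score"]

MAIN_TANKS = ("A", "B")
LIMITED_TANKS = ("C", "D")
INFINITE_TANKS = ("E", "F")


@dataclass
class Tank:
    name: str
    level: float
    capacity: Optional[float]  # None => infinite supply

    @property
    def infinite(self) -> bool:
        return self.capacity is None

    def headroom(self) -> float:
        if self.capacity is None:
            return math.inf
        return max(0.0, self.capacity - self.level)

    def available(self) -> float:
        return math.inf if self.capacity is None else max(0.0, self.level)


@dataclass
class Pump:
    id: int               # 1..8
    source: str
    destination: str
    flow_rate: float      # units / minute
    on: bool = False
    failed_until: Optional[float] = None

    def failed(self, t: float) -> bool:
        return self.failed_until is not None and t < self.failed_until


@dataclass
class ResmanState:
    tanks: dict[str, Tank]
    pumps: dict[int, Pump]
    drain_rate: float      # units / minute, per main tank
    target_level: float = 2000.0
    range: float = 1000.0
    rejected_toggles: list[tuple[float, int]] = field(default_factory=list)
    # cumulative bookkeeping for the conservation audit
    total_infinite_inflow: float = 0.0
    total_drained: float = 0.0


def build_resman_state(config) -> ResmanState:
    """Construct the tank/pump network from a :class:`ResmanConfig`."""
    tanks = {}
    for name in MAIN_TANKS:
        tanks[name] = Tank(name, config.main_start, config.main_capacity)
    for name in LIMITED_TANKS:
        tanks[name] = Tank(name, config.limited_start, config.limited_capacity)
    for name in INFINITE_TANKS:
        tanks[name] = Tank(name, 0.0, None)
    pumps = {}
    for i, ((src, dst), rate) in enumerate(zip(config.pump_topology,
                                               config.pump_flow_rates), start=1):
        pumps[i] = Pump(i, src, dst, rate)
    return ResmanState(tanks=tanks, pumps=pumps, drain_rate=config.drain_rate,
                       target_level=config.target_level, range=config.range)


def toggle_pump(state: ResmanState, pump_id: int, t: float) -> bool:
    """Flip a pump on/off.  A failed pump ignores the toggle (logged).

    Returns True if the state changed.
    """
    if pump_id not in state.pumps:
        raise ValueError(f"unknown pump id {pump_id}")
    pump = state.pumps[pump_id]
    if pump.failed(t):
        state.rejected_toggles.append((t, pump_id))
        return False
    pump.on = not pump.on
    return True


def fail_pump(state: ResmanState, pump_id: int, kind: str, t: float,
              duration: float) -> None:
    """Apply a scheduled pump failure or shutoff.

    A failure switches the pump off and locks it until ``t + duration``;
    a shutoff switches it off but leaves it immediately re-toggleable.
    """
    if pump_id not in state.pumps:
        raise ValueError(f"unknown pump id {pump_id}")
    if kind not in ("failure", "shutoff"):
        raise ValueError(f"unknown pump event kind {kind!r}")
    pump = state.pumps[pump_id]
    pump.on = False
    if kind == "failure":
        pump.failed_until = t + duration


def apply_flows(state: ResmanState, dt: float, t: float) -> None:
    """Advance pump transfers and main-tank drains by ``dt`` seconds.

    All active, un-failed pumps transfer ``rate * dt / 60`` units,
    simultaneously scaled down per source tank (insufficient fuel is split
    pro rata) and per destination tank (insufficient headroom likewise),
    so the result is order-independent within a tick.  Main tanks then
    drain at the configured rate, floored at empty.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    active = [p for p in state.pumps.values() if p.on and not p.failed(t)]
    desired = {p.id: p.flow_rate * dt / 60.0 for p in active}

    # scale by source availability
    for name, tank in state.tanks.items():
        if tank.infinite:
            continue
        out = [p for p in active if p.source == name]
        demand = sum(desired[p.id] for p in out)
        if demand > tank.available() and demand > 0:
            scale = tank.available() / demand
            for p in out:
                desired[p.id] *= scale

    # scale by destination headroom (reducing only ever frees source fuel)
    for name, tank in state.tanks.items():
        if tank.infinite:
            continue
        inflow = [p for p in active if p.destination == name]
        supply = sum(desired[p.id] for p in inflow)
        if supply > tank.headroom() and supply > 0:
            scale = tank.headroom() / supply
            for p in inflow:
                desired[p.id] *= scale

    for p in active:
        amount = desired[p.id]
        if amount <= 0:
            continue
        src, dst = state.tanks[p.source], state.tanks[p.destination]
        if not src.infinite:
            src.level = max(0.0, src.level - amount)
        else:
            state.total_infinite_inflow += amount
        if not dst.infinite:
            dst.level = min(dst.level + amount,
                            dst.capacity if dst.capacity is not None else math.inf)

    drain = state.drain_rate * dt / 60.0
    for name in MAIN_TANKS:
        tank = state.tanks[name]
        drained = min(tank.level, drain)
        tank.level -= drained
        state.total_drained += drained


def resman_score(level: float, target: float = 2000.0, rng_limit: float = 1000.0) -> float:
    """Signed normalized tank score: ``(level - target) / range * 100``.

    0 on target, positive above, negative below, clamped to [-100, 100].
    """
    if rng_limit <= 0:
        raise ValueError("range must be positive")
    return max(-100.0, min(100.0, (level - target) / rng_limit * 100.0))
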