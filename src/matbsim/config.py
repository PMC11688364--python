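"""Experiment configuration: validated parameter models, YAML round-trip,
colour profiles and the colour-vision-deficiency (CVD) simulation transform.

The configuration file replaces the point-and-click parameter-generation GUI
of the original desktop task batteries with a reviewable, versionable text
document.  One YAML file fully determines a session: durations, demand
levels, timeouts, flow rates, automation reliability/handoff/cue settings
and the master seed.  Together with the seed, the file is sufficient for
another lab to replicate the exact event placement of a study.

All models reject unknown keys so that typos in a config file fail loudly,
and every bound violation is reported by pydantic with the offending field
named.
"""

from __future__ import annotations

import functools
import importlib.resources
import math
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "ColorProfile",
    "SysmonConfig",
    "CommsConfig",
    "TrackingConfig",
    "ResmanConfig",
    "WorkloadConfig",
    "AutomationConfig",
    "AutomationTaskConfig",
    "ReliabilityEpoch",
    "ForcedWindow",
    "DemandConfig",
    "DemandRates",
    "EventCounts",
    "load_config",
    "save_config",
    "load_operator_spec",
    "apply_cvd",
    "apply_cvd_linear",
    "cvd_matrix_for",
    "builtin_cvd_matrices",
    "srgb_to_linear",
    "linear_to_srgb",
]

AUTOMATED_TASKS = ("sysmon", "comms", "tracking", "resman")


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed."""


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


# ---------------------------------------------------------------------------
# Per-task sections
# ---------------------------------------------------------------------------

class SysmonConfig(_StrictModel):
    """System-monitoring task: four lights answered by joystick buttons."""

    timeout: float = Field(5.0, gt=0, description="seconds a light stays on")
    n_lights: int = Field(4, ge=1, le=8)


class CommsConfig(_StrictModel):
    """Communications task: transcript stimuli with radio/channel/frequency."""

    timeout: float = Field(10.0, gt=0, description="response window after stimulus end, s")
    #: Stand-in for the mean spoken-stimulus duration of the classic WAV set;
    #: the stimulus here is a transcript event, not audio.
    stimulus_duration: float = Field(4.0, gt=0)
    confederate_rate: float = Field(0.25, ge=0, le=1,
                                    description="distractor calls added per own call")
    own_callsign: str = "NASA 504"
    chatter_mode: bool = False  # distractors become no-response noise events
    rt_reference: Literal["onset", "offset"] = "onset"

    @property
    def total_window(self) -> float:
        """Full active-light window: stimulus duration plus timeout."""
        return self.stimulus_duration + self.timeout


class TrackingConfig(_StrictModel):
    """Compensatory tracking: drifting cursor nulled against a fixed target."""

    range: float = Field(100.0, gt=0,
                         description="deviation (grid units) scoring as 100% error")
    speed_level: int = Field(2, ge=0, le=5)
    invert_x: bool = False
    invert_y: bool = False
    orientation: Literal["cursor-to-target", "target-to-cursor"] = "cursor-to-target"
    gain: float = Field(200.0, gt=0, description="full-deflection speed, grid units/s")


_CLASSIC_TOPOLOGY = [
    ["C", "A"], ["E", "A"], ["D", "B"], ["F", "B"],
    ["E", "C"], ["F", "D"], ["A", "B"], ["B", "A"],
]
_DEFAULT_FLOWS = [800.0, 600.0, 800.0, 600.0, 600.0, 600.0, 400.0, 400.0]


class ResmanConfig(_StrictModel):
    """Resource management: six tanks, eight pumps, drains and failures.

    Tanks A and B are the scored main tanks (target 2,000 units); C and D
    are limited supply tanks starting at 1,000 units; E and F hold infinite
    fuel.  Flow rates, capacities and drain rate are shipped artifact
    defaults in the classic layout and are fully overridable.
    """

    range: float = Field(1000.0, gt=0, description="tank deviation scoring as ±100")
    target_level: float = Field(2000.0, gt=0)
    drain_rate: float = Field(600.0, ge=0, description="units/min per main tank")
    pump_flow_rates: list[float] = Field(default_factory=lambda: list(_DEFAULT_FLOWS))
    pump_topology: list[list[str]] = Field(
        default_factory=lambda: [list(p) for p in _CLASSIC_TOPOLOGY])
    pump_failure_duration: float = Field(15.0, gt=0, description="seconds a failed pump is locked")
    main_capacity: float = Field(4000.0, gt=0)
    main_start: float = Field(2000.0, ge=0)
    limited_capacity: float = Field(2000.0, gt=0)
    limited_start: float = Field(1000.0, ge=0)

    @model_validator(mode="after")
    def _check_pumps(self) -> "ResmanConfig":
        if len(self.pump_flow_rates) != 8:
            raise ValueError("pump_flow_rates must list exactly 8 values")
        if any(r < 0 for r in self.pump_flow_rates):
            raise ValueError("pump_flow_rates must be non-negative")
        if len(self.pump_topology) != 8:
            raise ValueError("pump_topology must list exactly 8 (source, destination) pairs")
        tanks = {"A", "B", "C", "D", "E", "F"}
        for pair in self.pump_topology:
            if len(pair) != 2 or pair[0] not in tanks or pair[1] not in tanks:
                raise ValueError(f"pump_topology entry {pair!r} is not a valid tank pair")
        return self


class WorkloadConfig(_StrictModel):
    """Real-time subjective workload probe (modified ISA scale, 1..10)."""

    interval: float = Field(30.0, gt=0, description="seconds between prompts")
    window: float = Field(10.0, gt=0, description="seconds to respond")
    tone_frequency: float = Field(1000.0, gt=0)

    @model_validator(mode="after")
    def _window_fits(self) -> "WorkloadConfig":
        if self.window > self.interval:
            raise ValueError("workload window must not exceed workload interval")
        return self


# ---------------------------------------------------------------------------
# Automation
# ---------------------------------------------------------------------------

class ReliabilityEpoch(_StrictModel):
    time: float = Field(ge=0)
    reliability: float = Field(ge=0, le=100)


class ForcedWindow(_StrictModel):
    """A scheduled forced handoff.

    ``duration`` given: release by time (lock until time+duration).
    ``duration`` None: release when performance has stabilized above
    the task's release threshold for the configured dwell.
    """

    time: float = Field(ge=0)
    duration: Optional[float] = Field(None, gt=0)


class AutomationTaskConfig(_StrictModel):
    enabled: bool = False
    reliability: float = Field(100.0, ge=0, le=100,
                               description="target normalized score, 0..100")
    reliability_epochs: list[ReliabilityEpoch] = Field(default_factory=list)
    cue_threshold: Optional[float] = Field(None, ge=0, le=100)
    forced_windows: list[ForcedWindow] = Field(default_factory=list)
    forced_perf_threshold: Optional[float] = Field(None, ge=0, le=100)
    release_threshold: Optional[float] = Field(None, ge=0, le=100)
    release_dwell: float = Field(10.0, gt=0, description="seconds stabilized before release")
    perf_window: float = Field(30.0, gt=0, description="moving-average window, s")
    hysteresis_fraction: float = Field(0.5, ge=0, le=1,
                                       description="resman re-lock band as a fraction of the trigger band")


class AutomationConfig(_StrictModel):
    sysmon: AutomationTaskConfig = Field(default_factory=AutomationTaskConfig)
    comms: AutomationTaskConfig = Field(default_factory=AutomationTaskConfig)
    tracking: AutomationTaskConfig = Field(default_factory=AutomationTaskConfig)
    resman: AutomationTaskConfig = Field(default_factory=AutomationTaskConfig)

    def for_task(self, task: str) -> AutomationTaskConfig:
        return getattr(self, task)


# ---------------------------------------------------------------------------
# Demand
# ---------------------------------------------------------------------------

class DemandRates(_StrictModel):
    """Events per minute at one demand level."""

    sysmon: float = Field(0.0, ge=0)
    comms: float = Field(0.0, ge=0)
    resman_failures: float = Field(0.0, ge=0)
    resman_shutoffs: float = Field(0.0, ge=0)


class EventCounts(_StrictModel):
    """Explicit per-session event counts, overriding the demand table."""

    sysmon: int = Field(0, ge=0)
    comms: int = Field(0, ge=0)
    resman_failures: int = Field(0, ge=0)
    resman_shutoffs: int = Field(0, ge=0)


def _default_table() -> dict[int, DemandRates]:
    return {
        0: DemandRates(),
        1: DemandRates(sysmon=2, comms=1, resman_failures=0.5, resman_shutoffs=0.5),
        2: DemandRates(sysmon=4, comms=2, resman_failures=1, resman_shutoffs=1),
        3: DemandRates(sysmon=8, comms=3, resman_failures=2, resman_shutoffs=2),
    }


class DemandConfig(_StrictModel):
    """Ordinal demand levels and their explicit events-per-minute table.

    The mapping from demand level to event counts is not standardized across
    battery versions, so it is an explicit, overridable table rather than a
    built-in constant.  ``event_counts`` bypasses the table entirely.
    """

    sysmon: int = 2
    comms: int = 2
    resman: int = 2
    table: dict[int, DemandRates] = Field(default_factory=_default_table)
    event_counts: Optional[EventCounts] = None

    @model_validator(mode="after")
    def _levels_in_table(self) -> "DemandConfig":
        if self.event_counts is None:
            for task in ("sysmon", "comms", "resman"):
                level = getattr(self, task)
                if level not in self.table:
                    raise ValueError(f"demand level {level} for {task} missing from demand table")
        return self

    def counts_for(self, duration: float) -> EventCounts:
        """Resolve per-session event counts for a session of ``duration`` s."""
        if self.event_counts is not None:
            return self.event_counts
        minutes = duration / 60.0
        return EventCounts(
            sysmon=round(self.table[self.sysmon].sysmon * minutes),
            comms=round(self.table[self.comms].comms * minutes),
            resman_failures=round(self.table[self.resman].resman_failures * minutes),
            resman_shutoffs=round(self.table[self.resman].resman_shutoffs * minutes),
        )


# ---------------------------------------------------------------------------
# Colour profile and CVD simulation
# ---------------------------------------------------------------------------

CVDMode = Literal["none", "protan", "deutan", "tritan"]


class ColorProfile(_StrictModel):
    """Display colour assignments plus an optional CVD simulation matrix.

    ``cvd_matrix`` defaults to the shipped severity-1.0 matrix for
    ``cvd_mode``; supply an explicit 3x3 matrix to override.
    """

    elements: dict[str, tuple[float, float, float]] = Field(default_factory=dict)
    cvd_mode: CVDMode = "none"
    cvd_matrix: Optional[list[list[float]]] = None

    @field_validator("elements")
    @classmethod
    def _rgb_in_unit(cls, v):
        for name, rgb in v.items():
            if any(not (0.0 <= c <= 1.0) for c in rgb):
                raise ValueError(f"element {name!r} has RGB component outside [0, 1]")
        return v

    @field_validator("cvd_matrix")
    @classmethod
    def _matrix_shape(cls, v):
        if v is None:
            return v
        if len(v) != 3 or any(len(row) != 3 for row in v):
            raise ValueError("cvd_matrix must be 3x3")
        if not all(math.isfinite(x) for row in v for x in row):
            raise ValueError("cvd_matrix entries must be finite")
        return v


@functools.lru_cache(maxsize=1)
def builtin_cvd_matrices() -> dict[str, np.ndarray]:
    """Shipped severity-1.0 CVD matrices, loaded from package data."""
    text = (importlib.resources.files("matbsim") / "data" / "cvd_matrices.yaml").read_text()
    raw = yaml.safe_load(text)
    return {k: np.asarray(v, dtype=float) for k, v in raw.items()
            if k != "schema_version"}


def cvd_matrix_for(profile: ColorProfile) -> np.ndarray:
    if profile.cvd_matrix is not None:
        return np.asarray(profile.cvd_matrix, dtype=float)
    return builtin_cvd_matrices()[profile.cvd_mode]


def srgb_to_linear(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    return np.where(c <= 0.0031308, c * 12.92, 1.055 * np.maximum(c, 0.0) ** (1 / 2.4) - 0.055)


def apply_cvd_linear(color_linear, matrix) -> np.ndarray:
    """The linear stage of the CVD transform: plain matrix-vector product.

    Linear by construction: ``apply_cvd_linear(a*x, M) == a*apply_cvd_linear(x, M)``.
    """
    return np.asarray(matrix, dtype=float) @ np.asarray(color_linear, dtype=float)


def apply_cvd(color, profile: ColorProfile) -> tuple[float, float, float]:
    """Simulate colour-vision deficiency on one sRGB colour in [0,1]^3.

    The colour is decoded to linear RGB, multiplied by the profile's 3x3
    matrix, re-encoded to sRGB and clipped to the unit cube.
    """
    rgb = np.asarray(color, dtype=float)
    if rgb.shape != (3,) or np.any(rgb < 0) or np.any(rgb > 1):
        raise ValueError("color must be an RGB triple in [0,1]^3")
    lin = srgb_to_linear(rgb)
    out = apply_cvd_linear(lin, cvd_matrix_for(profile))
    out = np.clip(linear_to_srgb(out), 0.0, 1.0)
    return (float(out[0]), float(out[1]), float(out[2]))


# ---------------------------------------------------------------------------
# Top-level configuration
# ---------------------------------------------------------------------------

class OutputConfig(_StrictModel):
    directory: str = "."
    prefix: str = "session"


class SimulationConfig(_StrictModel):
    """Complete parameterization of one simulated session.

    ``duration`` is the only required field; every other value has a
    documented default.  The combination (config, master_seed) fully
    determines the generated schedule and, with an operator seed, the whole
    session log.
    """

    schema_version: int = 1
    duration: float = Field(gt=0, description="session length, simulated seconds")
    tick_dt: float = Field(0.05, gt=0, description="simulation step, s (~20 Hz)")
    master_seed: int = 0
    realtime: bool = False  # optional wall-clock pacing; batch mode by default
    demand: DemandConfig = Field(default_factory=DemandConfig)
    sysmon: SysmonConfig = Field(default_factory=SysmonConfig)
    comms: CommsConfig = Field(default_factory=CommsConfig)
    tracking: TrackingConfig = Field(default_factory=TrackingConfig)
    resman: ResmanConfig = Field(default_factory=ResmanConfig)
    workload: WorkloadConfig = Field(default_factory=WorkloadConfig)
    automation: AutomationConfig = Field(default_factory=AutomationConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)
    color_profile: Optional[ColorProfile] = None

    @property
    def n_ticks(self) -> int:
        return int(math.ceil(self.duration / self.tick_dt - 1e-9))


def load_config(path) -> SimulationConfig:
    """Load and validate a simulation config from a YAML file.

    Unknown keys are rejected; invariant violations raise a pydantic
    ``ValidationError`` naming the offending field.
    """
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return SimulationConfig.model_validate(raw)


def save_config(config: SimulationConfig, path) -> None:
    """Serialize a config to YAML such that ``load_config`` restores it."""
    payload = config.model_dump(mode="json")
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_operator_spec(path) -> dict:
    """Load an operator-model spec (same YAML dialect as the config file)."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    return raw
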