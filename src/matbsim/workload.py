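"""Real-time subjective workload probe (modified ISA scale).

At a configurable interval the probe prompts the operator — with a
1,000 Hz tone on the right speaker and a panel light change — to rate
their momentary workload on an incremental 1..10 scale.  The operator has
a 10 s window (default) to respond; afterwards the scale deactivates and
resets to 0 until the next prompt.  A missed prompt is logged as an
explicit missing response, never conflated with the idle 0 display.
"""

from __future__ import annotations

import wave
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["WorkloadResponse", "WorkloadProbeState", "probe_prompt",
           "probe_respond", "probe_expire", "synth_prompt_tone", "write_tone_wav"]


@dataclass
class WorkloadResponse:
    prompt_time: float
    value: Optional[int]   # 1..10, None if missed
    rt: Optional[float]    # None if missed


@dataclass
class WorkloadProbeState:
    interval: float = 30.0
    window: float = 10.0
    open_prompt: Optional[float] = None   # onset of the currently open window
    responses: list[WorkloadResponse] = field(default_factory=list)
    ignored_inputs: int = 0

    @property
    def display_value(self) -> int:
        """What the idle scale shows: 0 whenever no window is open."""
        if self.open_prompt is None:
            return 0
        answered = [r for r in self.responses if r.prompt_time == self.open_prompt]
        return answered[0].value if answered else 0


def probe_prompt(state: WorkloadProbeState, t: float) -> None:
    """Open a response window at a scheduled prompt time."""
    if state.open_prompt is not None:
        raise RuntimeError("previous workload window still open "
                           "(window must not exceed interval)")
    state.open_prompt = t


def probe_respond(state: WorkloadProbeState, value: int, t: float) -> bool:
    """Record a rating.  Returns True if accepted.

    Values outside 1..10 raise; a response with no open window is ignored
    and counted.  An accepted response closes the window and resets the
    scale to 0.
    """
    if not 1 <= value <= 10:
        raise ValueError(f"workload rating {value} outside 1..10")
    if state.open_prompt is None or t < state.open_prompt:
        state.ignored_inputs += 1
        return False
    state.responses.append(WorkloadResponse(state.open_prompt, value,
                                            t - state.open_prompt))
    state.open_prompt = None
    return True


def probe_expire(state: WorkloadProbeState, t: float) -> bool:
    """Close an unanswered window whose 10 s (configurable) ran out.

    Returns True if a missing response was recorded.
    """
    if state.open_prompt is not None and t - state.open_prompt >= state.window:
        state.responses.append(WorkloadResponse(state.open_prompt, None, None))
        state.open_prompt = None
        return True
    return False


def synth_prompt_tone(sample_rate: int, duration: float,
                      frequency: float = 1000.0, amplitude: float = 0.9) -> np.ndarray:
    """Synthesize the stereo prompt tone: a sinusoid on the right channel.

    Returns an (n, 2) float array in [-1, 1]; the left channel is silent,
    matching the right-speaker presentation of the prompt.  The sample
    rate must exceed the Nyquist bound for the tone frequency.
    """
    if sample_rate <= 2 * frequency:
        raise ValueError(f"sample rate {sample_rate} below Nyquist bound for {frequency} Hz")
    n = int(round(sample_rate * duration))
    t = np.arange(n) / sample_rate
    right = amplitude * np.sin(2 * np.pi * frequency * t)
    return np.column_stack([np.zeros(n), right])


def write_tone_wav(path, sample_rate: int = 44100, duration: float = 0.5,
                   frequency: float = 1000.0) -> None:
    """Write the prompt tone as a 16-bit stereo PCM WAV file."""
    samples = synth_prompt_tone(sample_rate, duration, frequency)
    pcm = np.clip(samples * 32767, -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(2)
        fh.setsampwidth(2)
        fh.setframerate(sample_rate)
        fh.writeframes(pcm.tobytes())
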