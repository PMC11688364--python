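"""Communications task: a discrete auditory-vigilance task on transcripts.

The original battery plays recorded speech of the form

    "NASA 504, NASA 504, turn your NAV1 radio to 126.475."

Here the semantics of the stimulus — callsign, radio, channel (digits
before the spoken "point") and frequency (digits after it) — are carried
by transcript events rather than audio playback.  The operator must select
the named radio and enter channel and frequency while the active-light
window is open (stimulus duration plus a timeout).  A call addressed to a
different callsign is a distractor and must be ignored; responding to one
is an error.

Accuracy is the number of correct elements out of three; the reaction-time
score follows ``(window - RT) / window * 100`` and is recorded only for a
fully correct response.

Transcript grammar (BNF):

    transcript ::= callsign ", " callsign ", turn your " radio
                   " radio to " channel "." frequency "."
    callsign   ::= word (" " word)*        ; both occurrences identical
    radio      ::= "NAV1" | "NAV2" | "COM1" | "COM2"
    channel    ::= digit digit digit
    frequency  ::= digit digit digit
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

__all__ = ["RADIOS", "CommEvent", "CommResponse", "CommRecord", "CommsTaskState",
           "TranscriptError", "parse_transcript", "generate_transcript",
           "comms_window", "comms_score", "evaluate_response"]

RADIOS = ("NAV1", "NAV2", "COM1", "COM2")


class TranscriptError(ValueError):
    """Raised for malformed transcripts; carries the failing position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass
class CommEvent:
    callsign: str
    is_own: bool
    radio: str
    channel: int     # 3-digit value spoken before "point"
    frequency: int   # 3-digit value spoken after "point"
    onset: float = 0.0
    stimulus_duration: float = 4.0
    timeout: float = 10.0
    is_noise: bool = False  # background-chatter stand-in; no response expected

    def __post_init__(self) -> None:
        if self.radio not in RADIOS:
            raise ValueError(f"radio {self.radio!r} not one of {RADIOS}")
        if not 0 <= self.channel <= 999:
            raise ValueError("channel outside [0, 999]")
        if not 0 <= self.frequency <= 999:
            raise ValueError("frequency outside [0, 999]")

    @property
    def total_window(self) -> float:
        return self.stimulus_duration + self.timeout

    @property
    def window_end(self) -> float:
        return self.onset + self.total_window


@dataclass
class CommResponse:
    """Operator entries; fields stay None until entered."""

    radio: Optional[str] = None
    channel: Optional[int] = None
    frequency: Optional[int] = None
    completed_at: Optional[float] = None

    def complete(self) -> bool:
        return None not in (self.radio, self.channel, self.frequency)


@dataclass
class CommRecord:
    event: CommEvent
    rt: Optional[float]   # None unless fully correct in-window
    accuracy: float       # fraction of 3 elements correct
    score: float
    outcome: str  # "correct" | "partial" | "miss" | "distractor_response" | "distractor_withheld"


@dataclass
class CommsTaskState:
    active: Optional[CommEvent] = None
    response: CommResponse = field(default_factory=CommResponse)
    records: list[CommRecord] = field(default_factory=list)
    distractor_errors: int = 0
    late_responses: int = 0

    def accuracy(self) -> Optional[float]:
        scored = [r for r in self.records if not r.outcome.startswith("distractor")]
        if not scored:
            return None
        return 100.0 * sum(r.accuracy for r in scored) / len(scored)


_TOKENS = [
    ("callsign", re.compile(r"[A-Za-z][A-Za-z0-9 ]*?(?=, )")),
    ("comma", re.compile(r", ")),
    ("callsign2", re.compile(r"[A-Za-z][A-Za-z0-9 ]*?(?=, )")),
    ("comma", re.compile(r", ")),
    ("turn", re.compile(r"turn your ")),
    ("radio", re.compile(r"NAV1|NAV2|COM1|COM2")),
    ("radio_to", re.compile(r" radio to ")),
    ("channel", re.compile(r"\d{3}")),
    ("point", re.compile(r"\.")),
    ("frequency", re.compile(r"\d{3}")),
    ("period", re.compile(r"\.")),
]


def parse_transcript(text: str) -> tuple[str, str, int, int]:
    """Parse a canonical transcript into (callsign, radio, channel, frequency).

    The channel is the three digits spoken before "point" (the decimal);
    the frequency the three digits after it.  Malformed input raises
    :class:`TranscriptError` with the character position of the failure.
    """
    pos = 0
    out: dict[str, str] = {}
    for name, pattern in _TOKENS:
        m = pattern.match(text, pos)
        if m is None:
            raise TranscriptError(f"expected {name}", pos)
        out[name] = m.group(0)
        pos = m.end()
    if pos != len(text.rstrip()):
        raise TranscriptError("unexpected trailing text", pos)
    if out["callsign"] != out["callsign2"]:
        raise TranscriptError("repeated callsign does not match the first", 0)
    return (out["callsign"], out["radio"], int(out["channel"]), int(out["frequency"]))


def generate_transcript(callsign: str, radio: str, channel: int, frequency: int) -> str:
    """Render the canonical transcript for a communications event."""
    if radio not in RADIOS:
        raise ValueError(f"radio {radio!r} not one of {RADIOS}")
    return f"{callsign}, {callsign}, turn your {radio} radio to {channel:03d}.{frequency:03d}."


def comms_window(event: CommEvent, t: float) -> bool:
    """Active-light flag: on from onset until stimulus end plus timeout."""
    return event.onset <= t < event.window_end


def comms_score(rt: float, total_window: float) -> float:
    """Normalized comms score: ``(window - rt) / window * 100``."""
    if total_window <= 0:
        raise ValueError("window must be positive")
    if rt < 0 or rt > total_window:
        raise ValueError(f"rt {rt} outside [0, {total_window}]")
    return (total_window - rt) / total_window * 100.0


def evaluate_response(event: CommEvent, response: CommResponse,
                      rt_reference: str = "onset") -> CommRecord:
    """Score a closing communications event against the entered response.

    Accuracy is matches/3.  The reaction time (and hence a nonzero score)
    is recorded only when all three elements are correct; partial and
    absent responses score 0.  Responses to distractor calls are errors and
    never scored.
    """
    matches = (int(response.radio == event.radio)
               + int(response.channel == event.channel)
               + int(response.frequency == event.frequency))
    accuracy = matches / 3.0
    if not event.is_own:
        entered = any(v is not None for v in
                      (response.radio, response.channel, response.frequency))
        return CommRecord(event, None, 0.0, 0.0,
                          "distractor_response" if entered else "distractor_withheld")
    if matches == 3 and response.completed_at is not None:
        origin = event.onset if rt_reference == "onset" else event.onset + event.stimulus_duration
        rt = max(0.0, min(response.completed_at - origin, event.total_window))
        return CommRecord(event, rt, 1.0, comms_score(rt, event.total_window), "correct")
    if matches > 0:
        return CommRecord(event, None, accuracy, 0.0, "partial")
    return CommRecord(event, None, 0.0, 0.0, "miss")
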