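"""Research-grade session output: raw per-tick table, markers, summaries,
and a pluggable stream-sink contract for live data synchronization.

The raw table has one row per simulation tick with a frozen, versioned
column registry (reaction times, normalized scores, accuracies, tank
values, workload responses, automation-state and discrete-task-loading
matrices).  Serialization is plain CSV, full double precision, period
decimal separator, no locale dependence — re-readable losslessly.

The wall-clock mean simulation-loop time is recorded in the session
metadata (JSON side-car), not in the raw table, so identical seeds yield
byte-identical raw/marker/summary files.

Live streaming (e.g. to a lab-streaming pipeline alongside physiological
recordings) is modeled as an abstract sink contract: anything with a
``push(time, channel, value)`` method can subscribe; the in-memory sink is
used in tests and the core engine has zero network dependencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "SCHEMA_VERSION", "SessionLog", "StreamSink",
           "InMemorySink", "write_raw", "read_raw", "write_markers",
           "write_summary", "summarize", "push_live", "write_session"]

SCHEMA_VERSION = 1

#: Frozen column registry of the raw per-tick table.
COLUMNS = [
    "time", "tick",
    "sysmon_rt", "sysmon_score", "sysmon_accuracy",
    "comms_rt", "comms_score", "comms_accuracy",
    "tracking_deviation", "tracking_score", "tracking_performance",
    "rm_tank1_value", "rm_tank1_score", "rm_tank2_value", "rm_tank2_score",
    "workload_value", "workload_rt",
    "auto_sysmon", "auto_comms", "auto_tracking", "auto_resman",
    "load_sysmon", "load_comms", "load_workload", "load_resman", "load_total",
]

SCORE_COLUMNS = [
    "sysmon_rt", "sysmon_score", "sysmon_accuracy",
    "comms_rt", "comms_score", "comms_accuracy",
    "tracking_deviation", "tracking_score", "tracking_performance",
    "rm_tank1_value", "rm_tank1_score", "rm_tank2_value", "rm_tank2_score",
    "workload_value", "workload_rt",
]


class StreamSink:
    """Contract for live consumers: receives time-ordered pushes per channel."""

    def push(self, t: float, channel: str, value) -> None:  # pragma: no cover
        raise NotImplementedError


@dataclass
class InMemorySink(StreamSink):
    """Reference sink storing every push; used by tests."""

    items: list[tuple[float, str, object]] = field(default_factory=list)

    def push(self, t: float, channel: str, value) -> None:
        self.items.append((t, channel, value))

    def channel(self, name: str) -> list[tuple[float, object]]:
        return [(t, v) for t, c, v in self.items if c == name]


@dataclass
class SessionLog:
    """Complete record of one session."""

    samples: pd.DataFrame
    markers: pd.DataFrame            # columns: time, label
    section_boundaries: list[float]
    meta: dict

    @classmethod
    def assemble(cls, rows: dict, markers: list[tuple[float, str]],
                 section_boundaries: list[float], meta: dict) -> "SessionLog":
        samples = pd.DataFrame({c: rows[c] for c in COLUMNS})
        mdf = pd.DataFrame(markers, columns=["time", "label"])
        return cls(samples=samples, markers=mdf,
                   section_boundaries=section_boundaries, meta=meta)

    def equivalent(self, other: "SessionLog") -> bool:
        """Determinism check: identical samples and markers (meta excluded —
        it carries wall-clock timing)."""
        return (self.samples.equals(other.samples)
                and self.markers.equals(other.markers)
                and self.section_boundaries == other.section_boundaries)


def write_raw(log: SessionLog, path) -> None:
    """One CSV row per tick, frozen header, full double precision."""
    log.samples.to_csv(path, index=False)


def read_raw(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != COLUMNS:
        raise ValueError(f"{path} header does not match the column registry")
    return df


def write_markers(log: SessionLog, path) -> None:
    log.markers.to_csv(path, index=False)


def _section_edges(log: SessionLog) -> list[tuple[float, float]]:
    duration = float(log.meta.get("duration", log.samples["time"].iloc[-1]
                                  if len(log.samples) else 0.0))
    cuts = [0.0] + sorted(log.section_boundaries) + [duration]
    return [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]


def summarize(log: SessionLog) -> pd.DataFrame:
    """Per-section and whole-session means of every score column.

    Sections are the marker-delimited appended segments; a session without
    demand transitions has a single section.  Means ignore the ticks where
    an event column has no completion (NaN).  Miss/error counts are
    derived from the accuracy and score columns of the raw table.
    """
    if log.samples.empty:
        return pd.DataFrame(columns=["section", "t_start", "t_end"] + SCORE_COLUMNS)
    rows = []
    sections = _section_edges(log) if len(log.samples) else []
    for label, (lo, hi) in ([("session", (0.0, np.inf))]
                            + [(f"section_{i}", edge) for i, edge in enumerate(sections)]):
        mask = (log.samples["time"] >= lo) & (log.samples["time"] < hi)
        sub = log.samples.loc[mask]
        row = {"section": label, "t_start": lo if np.isfinite(lo) else 0.0,
               "t_end": hi if np.isfinite(hi) else float(log.meta.get("duration", np.nan))}
        for col in SCORE_COLUMNS:
            vals = sub[col].to_numpy(dtype=float)
            finite = vals[~np.isnan(vals)]
            if finite.size == 0:
                row[col] = np.nan
            elif col.endswith("_accuracy"):
                # accuracy columns are running cumulative percentages: the
                # section's value is the last one, not the series mean
                row[col] = float(finite[-1])
            else:
                row[col] = float(np.nanmean(vals))
        row["sysmon_events"] = int(np.sum(~np.isnan(sub["sysmon_score"].to_numpy(float))))
        row["sysmon_misses"] = int(np.sum(sub["sysmon_score"].to_numpy(float) == 0.0))
        row["comms_events"] = int(np.sum(~np.isnan(sub["comms_score"].to_numpy(float))))
        row["workload_responses"] = int(np.sum(~np.isnan(sub["workload_value"].to_numpy(float))))
        rows.append(row)
    return pd.DataFrame(rows)


def write_summary(log: SessionLog, path) -> None:
    summarize(log).to_csv(path, index=False)


def push_live(log: SessionLog, sink: StreamSink) -> int:
    """Replay a completed log into a sink in time order; returns push count.

    Every marker and every per-tick score sample is pushed; the Start
    marker precedes all samples and Stop follows all.  Sink failures are
    surfaced to the caller, never swallowed into the log itself.
    """
    items: list[tuple[float, int, str, object]] = []
    for i, (_, m) in enumerate(log.markers.iterrows()):
        order = -1 if m["label"] == "Start" else (2 if m["label"] == "Stop" else 0)
        items.append((float(m["time"]), order, "marker", m["label"]))
    for _, row in log.samples.iterrows():
        for col in ("tracking_score", "rm_tank1_score", "rm_tank2_score"):
            items.append((float(row["time"]), 1, col, float(row[col])))
    items.sort(key=lambda x: (x[0], x[1]))
    for t, _, channel, value in items:
        sink.push(t, channel, value)
    return len(items)


def write_session(log: SessionLog, directory, prefix: str = "session") -> dict:
    """Write raw/markers/summary CSVs plus the metadata JSON side-car."""
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "raw": directory / f"{prefix}_raw.csv",
        "markers": directory / f"{prefix}_markers.csv",
        "summary": directory / f"{prefix}_summary.csv",
        "meta": directory / f"{prefix}_meta.json",
    }
    write_raw(log, paths["raw"])
    write_markers(log, paths["markers"])
    write_summary(log, paths["summary"])
    with open(paths["meta"], "w", encoding="utf-8") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, **log.meta}, fh, indent=2)
    return paths
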