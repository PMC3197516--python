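"""Event-log data model for resuscitation scenarios.

A scenario is recorded as a single timeline: the instant of every chest
compression downstroke plus a handful of annotated clinical events
(recognition of arrest, arrival of the cardiac arrest team, defibrillator
arrival, rhythm/pulse checks, shocks, ROSC or scripted scenario end).
All analysis downstream works on the canonical, validated :class:`EventLog`
produced here, with times in seconds re-based so that recognition of the
arrest ("Time 0") is 0.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import IO, Iterable, Union

import numpy as np

__all__ = [
    "EventKind",
    "AnnotatedEvent",
    "EventLog",
    "Phase",
    "EventLogError",
    "read_event_log",
    "write_event_log",
    "derive_phases",
    "normalize",
]


class EventKind(str, Enum):
    """Annotated clinical event types recognized on a scenario timeline."""

    ARREST_RECOGNIZED = "arrest_recognized"
    CPR_STARTED = "cpr_started"
    CALL_PLACED = "call_placed"
    DEFIB_ARRIVAL = "defib_arrival"
    FIRST_RHYTHM = "first_rhythm"
    RHYTHM_CHECK = "rhythm_check"
    SHOCK = "shock"
    PULSE_CHECK = "pulse_check"
    HANDOVER = "handover"
    ROSC = "rosc"
    SCENARIO_END = "scenario_end"


#: Events that may terminate the analysis horizon.
TERMINAL_KINDS = frozenset({EventKind.ROSC, EventKind.SCENARIO_END})

#: The record type used for compression rows in tabular files.
COMPRESSION_RECORD = "compression"


class EventLogError(ValueError):
    """Raised when a log violates the event-log invariants."""


@dataclass(frozen=True, order=True)
class AnnotatedEvent:
    """One annotated clinical event: a kind, a time (seconds), free-text detail."""

    time: float
    kind: EventKind
    detail: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.kind, EventKind):
            object.__setattr__(self, "kind", EventKind(self.kind))
        t = float(self.time)
        if not np.isfinite(t) or t < 0:
            raise EventLogError(f"event time must be finite and nonnegative, got {self.time!r}")
        object.__setattr__(self, "time", t)


@dataclass(frozen=True)
class Phase:
    """A labelled half-open window [start, end) of the scenario timeline."""

    label: str  # "overall", "first_responders" or "team"
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def window(self) -> tuple[float, float]:
        return (self.start, self.end)


@dataclass(frozen=True)
class EventLog:
    """A validated, time-normalized scenario timeline.

    ``compressions`` holds one time per compression downstroke (seconds,
    nondecreasing); ``events`` the annotated clinical events sorted by time.
    ``t0`` is recognition of arrest and ``t_end`` the terminal event (ROSC
    or scenario end); after normalization ``t0 == 0``.
    """

    scenario_id: str
    compressions: tuple[float, ...]
    events: tuple[AnnotatedEvent, ...]
    t0: float
    t_end: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "compressions", tuple(float(c) for c in self.compressions))
        object.__setattr__(self, "events", tuple(self.events))

    # -- convenience accessors -------------------------------------------------

    @property
    def duration(self) -> float:
        return self.t_end - self.t0

    def compression_array(self) -> np.ndarray:
        return np.asarray(self.compressions, dtype=float)

    def events_of_kind(self, kind: EventKind) -> tuple[AnnotatedEvent, ...]:
        kind = EventKind(kind)
        return tuple(e for e in self.events if e.kind is kind)

    def first_event(self, kind: EventKind) -> AnnotatedEvent | None:
        evs = self.events_of_kind(kind)
        return evs[0] if evs else None


def validate(log: EventLog) -> EventLog:
    """Check every event-log invariant; return the log unchanged if valid."""
    if not np.isfinite(log.t0) or not np.isfinite(log.t_end):
        raise EventLogError(f"{log.scenario_id}: t0/t_end must be finite")
    if not log.t0 < log.t_end:
        raise EventLogError(
            f"{log.scenario_id}: t0 ({log.t0}) must precede t_end ({log.t_end})"
        )
    starts = log.events_of_kind(EventKind.ARREST_RECOGNIZED)
    if len(starts) != 1:
        raise EventLogError(
            f"{log.scenario_id}: expected exactly one arrest_recognized event, found {len(starts)}"
        )
    terminals = [e for e in log.events if e.kind in TERMINAL_KINDS]
    if len(terminals) != 1:
        raise EventLogError(
            f"{log.scenario_id}: expected exactly one terminal event (rosc or scenario_end), "
            f"found {len(terminals)}"
        )
    comps = log.compression_array()
    if comps.size and (np.any(np.diff(comps) < 0)):
        idx = int(np.argmax(np.diff(comps) < 0))
        raise EventLogError(f"{log.scenario_id}: compressions not nondecreasing at index {idx + 1}")
    if comps.size and (comps[0] < log.t0 or comps[-1] > log.t_end):
        raise EventLogError(f"{log.scenario_id}: compression outside [t0, t_end]")
    times = [e.time for e in log.events]
    if any(b < a for a, b in zip(times, times[1:])):
        idx = next(i for i, (a, b) in enumerate(zip(times, times[1:])) if b < a)
        raise EventLogError(f"{log.scenario_id}: events not nondecreasing at index {idx + 1}")
    if any(t < log.t0 or t > log.t_end for t in times):
        raise EventLogError(f"{log.scenario_id}: event outside [t0, t_end]")
    if starts[0].time != log.t0:
        raise EventLogError(f"{log.scenario_id}: arrest_recognized time != t0")
    if terminals[0].time != log.t_end:
        raise EventLogError(f"{log.scenario_id}: terminal event time != t_end")
    if len(log.events_of_kind(EventKind.HANDOVER)) > 1:
        raise EventLogError(f"{log.scenario_id}: more than one handover event")
    return log


def normalize(log: EventLog) -> EventLog:
    """Re-base times so t0 = 0, sort, and validate. Idempotent."""
    shift = log.t0
    comps = tuple(sorted(c - shift for c in log.compressions))
    # sorted() is stable: same-time events keep their relative order
    events = tuple(
        sorted(
            (replace(e, time=e.time - shift) for e in log.events),
            key=lambda e: e.time,
        )
    )
    out = EventLog(
        scenario_id=log.scenario_id,
        compressions=comps,
        events=events,
        t0=0.0,
        t_end=log.t_end - shift,
    )
    return validate(out)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_HEADER = ("time_s", "event_type", "detail")

Source = Union[str, Path, IO[str]]


def _records_from_log(log: EventLog) -> list[tuple[float, str, str]]:
    """Merge compressions and annotated events into time-ordered records."""
    recs = [(e.time, e.kind.value, e.detail) for e in log.events]
    recs += [(c, COMPRESSION_RECORD, "") for c in log.compressions]
    # stable sort keeps same-time annotated events in canonical order
    recs.sort(key=lambda r: r[0])
    return recs


def _log_from_records(
    records: Iterable[tuple[int, float, str, str]], scenario_id: str
) -> EventLog:
    comps: list[float] = []
    events: list[AnnotatedEvent] = []
    last_t = -math.inf
    for idx, time_s, event_type, detail in records:
        try:
            t = float(time_s)
        except (TypeError, ValueError):
            raise EventLogError(f"record {idx}: non-numeric time {time_s!r}") from None
        if t < last_t:
            raise EventLogError(f"record {idx}: time {t} goes backwards (previous {last_t})")
        last_t = t
        if event_type == COMPRESSION_RECORD:
            comps.append(t)
        else:
            try:
                kind = EventKind(event_type)
            except ValueError:
                raise EventLogError(f"record {idx}: unknown event_type {event_type!r}") from None
            events.append(AnnotatedEvent(time=t, kind=kind, detail=detail or ""))
    starts = [e for e in events if e.kind is EventKind.ARREST_RECOGNIZED]
    if not starts:
        raise EventLogError("missing required event: arrest_recognized")
    terminals = [e for e in events if e.kind in TERMINAL_KINDS]
    if not terminals:
        raise EventLogError("missing required terminal event: rosc or scenario_end")
    log = EventLog(
        scenario_id=scenario_id,
        compressions=tuple(comps),
        events=tuple(sorted(events, key=lambda e: e.time)),
        t0=starts[0].time,
        t_end=terminals[0].time,
    )
    return normalize(log)


def read_event_log(source: Source, dialect: str = "csv", scenario_id: str | None = None) -> EventLog:
    """Read and validate one scenario log from a CSV or JSON stream/path.

    CSV files carry the header ``time_s,event_type,detail``; the JSON dialect
    is a list of objects with the same field names. Times are re-based so the
    arrest_recognized event sits at 0.
    """
    close = False
    if isinstance(source, (str, Path)):
        path = Path(source)
        if scenario_id is None:
            scenario_id = path.stem
        fh = path.open("r", encoding="utf-8")
        close = True
    else:
        fh = source
    if scenario_id is None:
        scenario_id = "scenario"
    try:
        if dialect == "csv":
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip() for h in header[:3]] != list(_HEADER):
                raise EventLogError(f"bad header: expected {','.join(_HEADER)}")
            rows = [
                (i, row[0], row[1], row[2] if len(row) > 2 else "")
                for i, row in enumerate(reader)
                if row
            ]
        elif dialect == "json":
            payload = json.load(fh)
            if isinstance(payload, dict):
                scenario_id = payload.get("scenario_id", scenario_id)
                payload = payload["records"]
            rows = [
                (i, rec["time_s"], rec["event_type"], rec.get("detail", ""))
                for i, rec in enumerate(payload)
            ]
        else:
            raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'json'")
    finally:
        if close:
            fh.close()
    return _log_from_records(rows, scenario_id)


def write_event_log(log: EventLog, sink: Source, dialect: str = "csv") -> None:
    """Write a log as records readable by :func:`read_event_log` (round trip)."""
    validate(log)
    recs = _records_from_log(log)
    close = False
    if isinstance(sink, (str, Path)):
        fh = Path(sink).open("w", encoding="utf-8", newline="")
        close = True
    else:
        fh = sink
    try:
        if dialect == "csv":
            writer = csv.writer(fh)
            writer.writerow(_HEADER)
            for t, kind, detail in recs:
                writer.writerow([repr(t), kind, detail])
        elif dialect == "json":
            json.dump(
                {
                    "scenario_id": log.scenario_id,
                    "records": [
                        {"time_s": t, "event_type": kind, "detail": detail}
                        for t, kind, detail in recs
                    ],
                },
                fh,
                indent=1,
            )
        else:
            raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'json'")
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# Phases
# ---------------------------------------------------------------------------

def derive_phases(log: EventLog) -> list[Phase]:
    """Split the timeline at the handover event.

    Always returns the overall phase [t0, t_end); when a (single) handover
    event is present, also the first-responder phase [t0, handover) and the
    team phase [handover, t_end), which partition the overall window.
    """
    validate(log)
    phases = [Phase("overall", log.t0, log.t_end)]
    handovers = log.events_of_kind(EventKind.HANDOVER)
    if handovers:
        h = handovers[0].time
        if not (log.t0 < h < log.t_end):
            raise EventLogError(
                f"{log.scenario_id}: handover at {h} not strictly inside ({log.t0}, {log.t_end})"
            )
        phases.append(Phase("first_responders", log.t0, h))
        phases.append(Phase("team", h, log.t_end))
    return phases
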