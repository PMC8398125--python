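"""Reading, writing and segmenting CASAS-dialect annotated sensor event logs.

A CASAS log is plain text, one sensor event per line::

    2011-05-15 02:52:00.000000  M004  ON   Bed_to_Toilet begin
    2011-05-15 02:52:03.000000  M004  OFF

Fields are date, time, sensor id, sensor state, and an optional two-token
activity annotation (label + ``begin``/``end`` marker).  Activity instances
are the maximal event runs bracketed by a matching begin/end pair.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Optional, Union

__all__ = [
    "SensorEvent",
    "ActivityInstance",
    "LogParseError",
    "parse_event_log",
    "write_event_log",
    "segment_activities",
    "PREV_NONE",
]

#: Sentinel used for the previous-activity label of the first instance in a
#: stream (no predecessor exists; downstream it encodes to the all-zero
#: one-hot so that no spurious context is injected).
PREV_NONE = "<none>"

_MARKERS = ("begin", "end")
_TS_FORMAT = "%Y-%m-%d %H:%M:%S.%f"


class LogParseError(ValueError):
    """Raised for a malformed log line; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped binary-sensor record.

    Parameters
    ----------
    timestamp
        Event date+time, microsecond resolution.
    sensor_id
        Sensor token; the prefix encodes the type (``M`` motion, ``D`` door,
        ``T`` temperature).
    state
        Raw state string: ``ON``/``OFF`` for binary sensors (plus malformed
        variants such as ``OF``/``OFF5`` in real logs, and ``OPEN``/``CLOSE``
        for doors), or a numeric reading for temperature sensors.
    activity, marker
        Optional annotation: the activity label and whether this event opens
        (``begin``) or closes (``end``) the instance.
    """

    timestamp: dt.datetime
    sensor_id: str
    state: str
    activity: Optional[str] = None
    marker: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.activity is None) != (self.marker is None):
            raise ValueError("activity and marker must be set together")
        if self.marker is not None and self.marker not in _MARKERS:
            raise ValueError(f"marker must be one of {_MARKERS}, got {self.marker!r}")

    @property
    def annotated(self) -> bool:
        return self.activity is not None


@dataclass
class ActivityInstance:
    """A labelled contiguous sensor-event subsequence.

    The first event carries the ``begin`` marker and the last the ``end``
    marker, both with ``activity == label``.  ``prev_label`` and the begin
    hour are the external context features; ``prev_label`` is filled by
    :func:`adlseq.preprocessing.attach_context` and defaults to the
    no-predecessor sentinel.
    """

    label: str
    events: list  # list[SensorEvent]
    prev_label: str = PREV_NONE

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("ActivityInstance requires at least one event")
        first, last = self.events[0], self.events[-1]
        if first.marker != "begin" or first.activity != self.label:
            raise ValueError("first event must carry the begin marker of the label")
        if last.marker != "end" or last.activity != self.label:
            raise ValueError("last event must carry the end marker of the label")

    @property
    def begin_ts(self) -> dt.datetime:
        return self.events[0].timestamp

    @property
    def begin_hour(self) -> int:
        return self.begin_ts.hour

    def __len__(self) -> int:
        return len(self.events)


def _parse_line(lineno: int, line: str) -> SensorEvent:
    fields = line.split()
    if len(fields) < 4:
        raise LogParseError(lineno, f"expected >=4 fields, got {len(fields)}")
    if len(fields) not in (4, 6):
        raise LogParseError(
            lineno, f"expected 4 or 6 fields (annotation is 'label marker'), got {len(fields)}"
        )
    try:
        ts = dt.datetime.strptime(f"{fields[0]} {fields[1]}", _TS_FORMAT)
    except ValueError:
        # real Aruba lines sometimes omit fractional seconds
        try:
            ts = dt.datetime.strptime(f"{fields[0]} {fields[1]}", "%Y-%m-%d %H:%M:%S")
        except ValueError as exc:
            raise LogParseError(lineno, f"unparseable timestamp {fields[0]} {fields[1]}") from exc
    activity = marker = None
    if len(fields) == 6:
        activity, marker = fields[4], fields[5]
        if marker not in _MARKERS:
            raise LogParseError(lineno, f"unknown annotation marker {marker!r}")
    return SensorEvent(ts, fields[2], fields[3], activity, marker)


def parse_event_log(source: Union[str, IO[str], Iterable[str]]) -> list:
    """Parse a CASAS-dialect log into a list of :class:`SensorEvent`.

    ``source`` may be a path, an open text stream, or an iterable of lines.
    Lines are split on arbitrary whitespace runs (real logs mix tabs and
    spaces).  Blank lines are ignored.  Non-decreasing timestamps are NOT
    enforced: real logs contain clock jitter, so violations raise a warning
    and file order is kept.
    """
    if isinstance(source, str):
        with open(source) as fh:
            return parse_event_log(fh)
    events = []
    prev_ts = None
    for lineno, line in enumerate(source, start=1):
        if not line.strip():
            continue
        ev = _parse_line(lineno, line)
        if prev_ts is not None and ev.timestamp < prev_ts:
            warnings.warn(
                f"non-monotone timestamp at line {lineno} "
                f"({ev.timestamp} < {prev_ts}); keeping file order",
                stacklevel=2,
            )
        prev_ts = ev.timestamp
        events.append(ev)
    return events


def write_event_log(events: Iterable[SensorEvent], stream: Optional[IO[str]] = None,
                    sep: str = "\t") -> Optional[str]:
    """Serialize events back to the CASAS dialect.

    Fields are joined with ``sep`` (a single tab by default); fractional
    seconds are always written with 6 digits so that parse/write round-trips
    are byte-identical on generated logs.  If ``stream`` is None the log is
    returned as a string.
    """
    lines = []
    for ev in events:
        fields = [ev.timestamp.strftime("%Y-%m-%d"), ev.timestamp.strftime("%H:%M:%S.%f"),
                  ev.sensor_id, ev.state]
        if ev.annotated:
            fields += [ev.activity, ev.marker]
        lines.append(sep.join(fields))
    text = "".join(line + "\n" for line in lines)
    if stream is None:
        return text
    stream.write(text)
    return None


def segment_activities(events: Iterable[SensorEvent]) -> list:
    """Cut an annotated event stream into :class:`ActivityInstance` objects.

    Every ``begin``…``end`` pair of the same label yields one instance holding
    all events from the begin event through the end event inclusive.  Events
    outside any span are dropped (only annotated instances are classified).
    A begin without a matching end (or an end without a begin) discards that
    span with a warning.  Overlapping spans of different labels raise — the
    single-resident logs this package targets do not nest annotations.
    """
    instances = []
    open_label: Optional[str] = None
    buffer: list = []
    for ev in events:
        if ev.marker == "begin":
            if open_label is not None:
                raise ValueError(
                    f"overlapping activity spans: {ev.activity!r} begins at "
                    f"{ev.timestamp} while {open_label!r} is still open"
                )
            open_label = ev.activity
            buffer = [ev]
        elif ev.marker == "end":
            if open_label is None:
                warnings.warn(
                    f"end marker for {ev.activity!r} at {ev.timestamp} without a "
                    "matching begin; span discarded",
                    stacklevel=2,
                )
                continue
            if ev.activity != open_label:
                raise ValueError(
                    f"overlapping activity spans: {ev.activity!r} ends at "
                    f"{ev.timestamp} inside an open {open_label!r} span"
                )
            buffer.append(ev)
            instances.append(ActivityInstance(open_label, buffer))
            open_label, buffer = None, []
        elif open_label is not None:
            buffer.append(ev)
        # unannotated events outside a span are dropped
    if open_label is not None:
        warnings.warn(
            f"dangling begin for {open_label!r} at end of log; span discarded",
            stacklevel=2,
        )
    return instances
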