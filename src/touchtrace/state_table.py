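"""Per-timestamp digit-state table ("digit positions" export).

The raw event stream records only the digits that changed; analysis is far
easier over a table that makes the state of all ten potential inputs
explicit at every recorded timestamp.  Event codes in the table are
0:UP, 1:DOWN, 2:MOVE, 3:STAT (stationary — in contact, no event at this
timestamp, position carried forward) and -1:ERROR (sensor overload).

The export dialect is semicolon-separated: the timestamp, then per digit
``event;posX;posY`` with empty fields when that input has no state at the
time.  Rows are event-driven: one row per distinct raw event timestamp (no
fixed-rate resampling; "no event, no data").
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby

from .log_io import Action, TouchLog

__all__ = [
    "EVENT_UP",
    "EVENT_DOWN",
    "EVENT_MOVE",
    "EVENT_STAT",
    "EVENT_ERROR",
    "DigitStateRow",
    "expand",
    "resample_uniform",
    "write_digit_positions",
    "parse_digit_positions",
]

EVENT_UP = 0
EVENT_DOWN = 1
EVENT_MOVE = 2
EVENT_STAT = 3
EVENT_ERROR = -1

N_DIGITS = 10

#: events that mean "this digit is in use (stationary or moving)"
IN_USE = frozenset({EVENT_DOWN, EVENT_MOVE, EVENT_STAT})


@dataclass
class DigitStateRow:
    """State of all ten potential inputs at one timestamp.

    ``events[d]`` is the event code for digit slot ``d`` or None;
    ``positions[d]`` is its (x, y) or None.  A STAT digit carries its last
    known position.
    """

    t: int
    events: list[int | None]
    positions: list[tuple[float, float] | None]

    def digits_in_use(self) -> list[int]:
        return [d for d, e in enumerate(self.events) if e in IN_USE]

    @property
    def n_digits_in_use(self) -> int:
        return len(self.digits_in_use())


def expand(log: TouchLog) -> list[DigitStateRow]:
    """Expand a raw event stream into one row per distinct event timestamp.

    Every raw UP/DOWN/MOVE appears in exactly one row.  Digits in contact
    without an event at a timestamp are emitted as STAT at their last known
    position; digits not in contact are None.  A sensor-overload event
    marks all currently-down digits ERROR in that row and force-closes
    their contact segments.
    """
    rows: list[DigitStateRow] = []
    # digit -> last known position while in contact
    contact: dict[int, tuple[float, float]] = {}
    for t, group in groupby(log.events, key=lambda e: e.t):
        events: list[int | None] = [None] * N_DIGITS
        positions: list[tuple[float, float] | None] = [None] * N_DIGITS
        overload = False
        for ev in group:
            if ev.action is Action.OVERLOAD:
                overload = True
                continue
            pos = (ev.x, ev.y)
            d = ev.input_id
            if ev.action is Action.DOWN:
                events[d], positions[d] = EVENT_DOWN, pos
                contact[d] = pos
            elif ev.action is Action.MOVE:
                events[d], positions[d] = EVENT_MOVE, pos
                contact[d] = pos
            elif ev.action is Action.UP:
                events[d], positions[d] = EVENT_UP, pos
                contact.pop(d, None)
        if overload:
            for d in list(contact):
                events[d], positions[d] = EVENT_ERROR, contact[d]
                del contact[d]
        for d, pos in contact.items():
            if events[d] is None:
                events[d], positions[d] = EVENT_STAT, pos
        if any(e is not None for e in events):
            rows.append(DigitStateRow(t=t, events=events, positions=positions))
    return rows


def resample_uniform(rows: list[DigitStateRow], dt: int) -> list[DigitStateRow]:
    """Derived fixed-rate view (position carried forward), for histogramming.

    Not part of the export dialect: the original table is event-driven.
    Each output row at ``t0 + k*dt`` carries the in-contact digits of the
    most recent event row as STAT at their then-current positions.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not rows:
        return []
    out: list[DigitStateRow] = []
    i = 0
    contact: dict[int, tuple[float, float]] = {}
    for t in range(rows[0].t, rows[-1].t + 1, dt):
        while i < len(rows) and rows[i].t <= t:
            row = rows[i]
            for d in range(N_DIGITS):
                e = row.events[d]
                if e in (EVENT_DOWN, EVENT_MOVE, EVENT_STAT):
                    contact[d] = row.positions[d]
                elif e in (EVENT_UP, EVENT_ERROR):
                    contact.pop(d, None)
            i += 1
        events: list[int | None] = [None] * N_DIGITS
        positions: list[tuple[float, float] | None] = [None] * N_DIGITS
        for d, pos in contact.items():
            events[d], positions[d] = EVENT_STAT, pos
        out.append(DigitStateRow(t=t, events=events, positions=positions))
    return out


_HEADER = "timeStamp;" + ";".join(
    f"event-Digit{d};posX-Digit{d};posY-Digit{d}" for d in range(N_DIGITS)
)


def _fmt(v: float) -> str:
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def write_digit_positions(rows: list[DigitStateRow]) -> str:
    """Serialize rows to the semicolon dialect (with a header line)."""
    lines = [_HEADER]
    for row in rows:
        fields = [str(row.t)]
        for d in range(N_DIGITS):
            if row.events[d] is None:
                fields += ["", "", ""]
            else:
                x, y = row.positions[d]
                fields += [str(row.events[d]), _fmt(x), _fmt(y)]
        lines.append(";".join(fields))
    return "\n".join(lines) + "\n"


def parse_digit_positions(text: str) -> list[DigitStateRow]:
    """Parse the semicolon dialect back into rows (round-trip identity)."""
    rows: list[DigitStateRow] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line or line.startswith("timeStamp"):
            continue
        fields = line.split(";")
        if len(fields) != 1 + 3 * N_DIGITS:
            raise ValueError(
                f"line {lineno}: expected {1 + 3 * N_DIGITS} semicolon-separated fields, "
                f"got {len(fields)}"
            )
        t = int(fields[0])
        events: list[int | None] = [None] * N_DIGITS
        positions: list[tuple[float, float] | None] = [None] * N_DIGITS
        for d in range(N_DIGITS):
            e, x, y = fields[1 + 3 * d : 4 + 3 * d]
            if e == "":
                continue
            events[d] = int(e)
            positions[d] = (float(x), float(y))
        rows.append(DigitStateRow(t=t, events=events, positions=positions))
    return rows
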