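"""Reader/writer/validator for the raw multitouch logger file format.

A capacitive-tablet logger records each touch event as a comma-separated
quintuple ``InputID,locationX,locationY,timeStamp,touchAction``.  Action
codes are ``0`` (digit UP), ``1`` (digit DOWN), ``2`` (digit MOVE), ``-1``
(sensor overload) and ``*`` (calibration record).  Input IDs 0-9 encode
contact order, not finger identity: an ID is held for the duration of one
continuous contact and freed on lift-off.

Calibration records precede all touch events.  They reuse the quintuple
grammar with the action field set to ``*`` and the input-ID field reused as
a corner index 0-3 (default corner order: top-left, top-right, bottom-left,
bottom-right; configurable).  Optional ``#`` comment lines before the
calibration block carry ``key=value`` metadata (participant, stimulus,
device resolution).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

__all__ = [
    "Action",
    "TouchEvent",
    "CalibrationTouch",
    "TouchLog",
    "LogFormatError",
    "LogValidationError",
    "ValidationReport",
    "DEFAULT_CORNER_ORDER",
    "parse_log",
    "write_log",
    "validate_log",
]

DEFAULT_CORNER_ORDER = ("top-left", "top-right", "bottom-left", "bottom-right")

#: sentinel input-ID used on sensor-overload rows (no digit is addressed)
OVERLOAD_ID = -1


class Action(enum.Enum):
    """Touch action codes as serialized in the raw log."""

    UP = 0
    DOWN = 1
    MOVE = 2
    OVERLOAD = -1
    CALIBRATION = "*"

    @property
    def code(self) -> str:
        """Serialized form of the action field."""
        return "*" if self is Action.CALIBRATION else str(self.value)

    @classmethod
    def from_code(cls, code: str) -> "Action":
        code = code.strip()
        if code == "*":
            return cls.CALIBRATION
        # tolerate the unicode minus that sometimes survives copy/paste
        code = code.replace("−", "-")
        return cls(int(code))


class LogFormatError(ValueError):
    """Malformed raw-log content (carries the offending line number)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class LogValidationError(ValueError):
    """A log violates a structural invariant (strict mode only)."""


@dataclass(frozen=True)
class TouchEvent:
    """One raw quintuple: a single touch event/state.

    Coordinates are device screen pixels, origin top-left, y downward;
    ``t`` is the system timestamp in milliseconds.
    """

    input_id: int
    x: float
    y: float
    t: int
    action: Action

    def __post_init__(self):
        if self.action in (Action.UP, Action.DOWN, Action.MOVE):
            if not 0 <= self.input_id <= 9:
                raise LogValidationError(
                    f"input_id {self.input_id} outside 0-9 for action {self.action.name}"
                )


@dataclass(frozen=True)
class CalibrationTouch:
    """A corner-calibration record: device point for one stimulus corner."""

    corner_index: int
    x: float
    y: float
    t: int
    corner_label: str = ""


@dataclass
class TouchLog:
    """A parsed trial: calibration block, time-ordered events, metadata."""

    calibration: list[CalibrationTouch] = field(default_factory=list)
    events: list[TouchEvent] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)

    @property
    def duration_ms(self) -> int:
        if not self.events:
            return 0
        return self.events[-1].t - self.events[0].t

    def calibration_points(self) -> list[tuple[float, float]]:
        """Device points in corner-index order (for geometry.fit_transform)."""
        return [(c.x, c.y) for c in sorted(self.calibration, key=lambda c: c.corner_index)]


def _fmt(v: float) -> str:
    """Serialize a coordinate: integral floats print as ints (as the logger does)."""
    f = float(v)
    return str(int(f)) if f.is_integer() else repr(f)


def parse_log(
    text: str,
    strict: bool = False,
    corner_order: tuple[str, ...] = DEFAULT_CORNER_ORDER,
) -> TouchLog:
    """Parse raw log content into a :class:`TouchLog`.

    Parameters
    ----------
    text:
        Line-oriented, comma-separated log content (LF or CRLF).
    strict:
        If true, malformed lines, a missing calibration block, and
        non-monotone timestamps raise; otherwise malformed lines are
        skipped with a warning and ordering problems warn only.
    corner_order:
        Labels attached to calibration corner indices 0-3.
    """
    log = TouchLog()
    seen_event = False
    prev_t: int | None = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                log.meta[key.strip()] = val.strip()
            continue
        parts = [p.strip() for p in line.split(",")]
        try:
            if len(parts) != 5:
                raise LogFormatError(f"expected 5 comma-separated fields, got {len(parts)}", lineno)
            try:
                action = Action.from_code(parts[4])
                ident = int(parts[0])
                x, y = float(parts[1]), float(parts[2])
                t = int(float(parts[3]))
            except (ValueError, KeyError) as exc:
                raise LogFormatError(f"cannot parse fields: {exc}", lineno) from exc
            if action is Action.CALIBRATION:
                if seen_event and strict:
                    raise LogValidationError(
                        f"line {lineno}: calibration record after touch events"
                    )
                label = corner_order[ident] if 0 <= ident < len(corner_order) else ""
                log.calibration.append(CalibrationTouch(ident, x, y, t, label))
                continue
            try:
                ev = TouchEvent(ident, x, y, t, action)
            except LogValidationError as exc:
                raise LogFormatError(str(exc), lineno) from exc
        except LogFormatError:
            if strict:
                raise
            warnings.warn(f"skipping malformed line {lineno}: {line!r}", stacklevel=2)
            continue
        if prev_t is not None and ev.t < prev_t:
            msg = f"line {lineno}: timestamp {ev.t} decreases (previous {prev_t})"
            if strict:
                raise LogValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        prev_t = ev.t
        seen_event = True
        log.events.append(ev)
    if strict and not log.calibration:
        raise LogValidationError("no calibration records found (strict mode)")
    return log


def write_log(log: TouchLog) -> str:
    """Serialize a :class:`TouchLog` back to raw text.

    ``parse_log(write_log(log))`` reproduces the calibration block, event
    list and metadata exactly.
    """
    lines: list[str] = []
    for key, val in log.meta.items():
        lines.append(f"# {key}={val}")
    for cal in log.calibration:
        lines.append(f"{cal.corner_index},{_fmt(cal.x)},{_fmt(cal.y)},{cal.t},*")
    for ev in log.events:
        if not isinstance(ev.action, Action) or ev.action is Action.CALIBRATION:
            raise LogValidationError(f"invalid event action {ev.action!r} in event list")
        lines.append(f"{ev.input_id},{_fmt(ev.x)},{_fmt(ev.y)},{ev.t},{ev.action.code}")
    return "\n".join(lines) + ("\n" if lines else "")


@dataclass
class ValidationReport:
    """Report-only invariant check results plus basic statistics."""

    violations: list[str] = field(default_factory=list)
    n_events: int = 0
    n_calibration: int = 0
    duration_ms: int = 0
    segments_per_id: dict[int, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_log(log: TouchLog) -> ValidationReport:
    """Check :class:`TouchLog` invariants without raising.

    Checks per-ID event ordering (DOWN, MOVE*, UP), timestamp monotonicity,
    calibration count, and the overload contract (no MOVE for any ID until
    contacts are re-established after a sensor overload).
    """
    rep = ValidationReport(
        n_events=len(log.events),
        n_calibration=len(log.calibration),
        duration_ms=log.duration_ms,
    )
    if log.calibration and len(log.calibration) != 4:
        rep.violations.append(f"expected 4 calibration records, found {len(log.calibration)}")
    in_contact: dict[int, bool] = {}
    prev_t: int | None = None
    for i, ev in enumerate(log.events):
        if prev_t is not None and ev.t < prev_t:
            rep.violations.append(f"event {i}: timestamp {ev.t} decreases (previous {prev_t})")
        prev_t = ev.t
        if ev.action is Action.OVERLOAD:
            # sensor overload implicitly breaks all contacts
            in_contact = {}
            continue
        down = in_contact.get(ev.input_id, False)
        if ev.action is Action.DOWN:
            if down:
                rep.violations.append(f"event {i}: DOWN for ID {ev.input_id} already in contact")
            in_contact[ev.input_id] = True
            rep.segments_per_id[ev.input_id] = rep.segments_per_id.get(ev.input_id, 0) + 1
        elif ev.action is Action.MOVE:
            if not down:
                rep.violations.append(f"event {i}: orphan MOVE for ID {ev.input_id} (no DOWN)")
        elif ev.action is Action.UP:
            if not down:
                rep.violations.append(f"event {i}: orphan UP for ID {ev.input_id} (no DOWN)")
            in_contact[ev.input_id] = False
    return rep
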