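"""Tactile protocol analysis: action taxonomy, stroke segmentation and
automatic rule-based gesture coding.

The taxonomy distinguishes elementary actions within an object (trace,
glance, fix, brush, scan-within, tap, hover), across objects (scan, comb,
skim, slideTo, jumpTo), across-and-within (span), and above/away from the
display (park, break).  Each action admits particular duration classes:
short (< 0.5 s), medium (0.5-2 s, boundaries inclusive) and long (> 2 s).

Manual coding proceeds in two passes — a coarse first pass segmenting the
trial at every change of area-of-interest occupancy, then detailed coding
of elementary actions nested under selected first-pass lines.  The
automatic classifier implemented here codes strokes (DOWN..UP runs per
input ID) by explicit geometric/kinematic rules with documented, tunable
thresholds; off-surface movements are not captured by the logger, so
park/break can only be flagged as indeterminate candidates, and hand/finger
identity (obtainable only from video) defaults to unknown.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

from shapely.geometry import LineString, Point as ShapelyPoint

from .geometry import AoiCell, AoiMap, assign_aoi
from .state_table import (
    EVENT_DOWN,
    EVENT_ERROR,
    EVENT_MOVE,
    EVENT_STAT,
    EVENT_UP,
    N_DIGITS,
    DigitStateRow,
)

__all__ = [
    "ActionLabel",
    "TimeScale",
    "Hand",
    "RuleParams",
    "Stroke",
    "GestureCode",
    "InterStrokeEvent",
    "SpanEvent",
    "classify_duration",
    "is_admissible",
    "segment_strokes",
    "classify_stroke",
    "detect_inter_stroke",
    "detect_span",
    "first_pass_coding",
    "detailed_coding",
    "auto_code",
    "gesture_time_budget",
    "export_coding",
    "import_coding",
    "mins_secs",
]


class TimeScale(enum.Enum):
    SHORT = "s"
    MEDIUM = "m"
    LONG = "l"


def classify_duration(d_ms: float) -> TimeScale:
    """Duration class: short < 500 ms, medium 500-2,000 ms (inclusive at
    both boundaries), long > 2,000 ms.  The classes partition (0, inf)."""
    if d_ms < 0:
        raise ValueError("duration must be non-negative")
    if d_ms < 500:
        return TimeScale.SHORT
    if d_ms <= 2000:
        return TimeScale.MEDIUM
    return TimeScale.LONG


class ActionLabel(enum.Enum):
    # within an object
    TRACE = "trace"
    GLANCE = "glance"
    FIX = "fix"
    BRUSH = "brush"
    SCAN_WITHIN = "scan_within"
    TAP = "tap"
    HOVER = "hover"
    # across objects
    SCAN = "scan"
    COMB = "comb"
    SKIM = "skim"
    SLIDE_TO = "slide_to"
    JUMP_TO = "jump_to"
    # across and within
    SPAN = "span"
    # above or away from the display (unobservable from the log alone)
    PARK = "park"
    BREAK = "break"


#: taxonomy category per label
CATEGORY: dict[ActionLabel, str] = {
    ActionLabel.TRACE: "within",
    ActionLabel.GLANCE: "within",
    ActionLabel.FIX: "within",
    ActionLabel.BRUSH: "within",
    ActionLabel.SCAN_WITHIN: "within",
    ActionLabel.TAP: "within",
    ActionLabel.HOVER: "within",
    ActionLabel.SCAN: "across",
    ActionLabel.COMB: "across",
    ActionLabel.SKIM: "across",
    ActionLabel.SLIDE_TO: "across",
    ActionLabel.JUMP_TO: "across",
    ActionLabel.SPAN: "across_and_within",
    ActionLabel.PARK: "off_display",
    ActionLabel.BREAK: "off_display",
}

#: admissible duration classes per label
ADMISSIBLE_SCALES: dict[ActionLabel, frozenset[TimeScale]] = {
    ActionLabel.TRACE: frozenset({TimeScale.SHORT, TimeScale.MEDIUM, TimeScale.LONG}),
    ActionLabel.GLANCE: frozenset({TimeScale.SHORT}),
    ActionLabel.FIX: frozenset({TimeScale.MEDIUM, TimeScale.LONG}),
    ActionLabel.BRUSH: frozenset({TimeScale.MEDIUM, TimeScale.LONG}),
    ActionLabel.SCAN_WITHIN: frozenset({TimeScale.SHORT}),
    ActionLabel.TAP: frozenset({TimeScale.SHORT}),
    ActionLabel.HOVER: frozenset({TimeScale.MEDIUM, TimeScale.LONG}),
    ActionLabel.SCAN: frozenset({TimeScale.MEDIUM, TimeScale.LONG}),
    ActionLabel.COMB: frozenset({TimeScale.MEDIUM, TimeScale.LONG}),
    ActionLabel.SKIM: frozenset({TimeScale.SHORT, TimeScale.MEDIUM}),
    ActionLabel.SLIDE_TO: frozenset({TimeScale.SHORT}),
    ActionLabel.JUMP_TO: frozenset({TimeScale.SHORT}),
    ActionLabel.SPAN: frozenset({TimeScale.SHORT}),
    ActionLabel.PARK: frozenset({TimeScale.MEDIUM, TimeScale.LONG}),
    ActionLabel.BREAK: frozenset({TimeScale.MEDIUM, TimeScale.LONG}),
}


def is_admissible(label: ActionLabel, duration_ms: float) -> bool:
    return classify_duration(duration_ms) in ADMISSIBLE_SCALES[label]


class Hand(enum.Enum):
    LH = "LH"
    RH = "RH"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class RuleParams:
    """Tunable thresholds for the automatic classifier.

    The taxonomy's definitions are qualitative; these defaults make them
    operational and are all configurable.  Units: pixels, milliseconds,
    pixels/second.
    """

    stationary_radius: float = 8.0  # max wander of a "stationary" touch
    tap_max: float = 150.0  # max duration of a momentary point touch
    pause_speed: float = 40.0  # below this, a digit counts as paused
    pause_min_ms: float = 120.0  # minimum pause length that counts
    hand_radius: float = 300.0  # concurrent touches this close = one hand
    jump_max: float = 1000.0  # max off-surface gap of a jumpTo
    hover_min: float = 500.0  # min off-surface gap of a hover
    offsurface_min: float = 2000.0  # gaps beyond this flag park/break
    min_move: float = 3.0  # displacement below this is jitter
    reversal_cos: float = -0.5  # direction change sharper than 120 deg
    perimeter_tol: float = 18.0  # max distance to outline for a trace
    glance_transit_frac: float = 0.6  # net displacement/cell size for a transit
    level3_frac: float = 0.25  # extent fraction below which level = 3
    level2_frac: float = 0.75  # extent fraction below which level = 2


@dataclass
class Stroke:
    """One contact segment (DOWN..UP) of one input ID, with features."""

    input_id: int
    samples: list[tuple[int, float, float]]
    unclosed: bool = False  # log ended before UP
    overload_closed: bool = False  # force-closed by a sensor overload

    @property
    def t0(self) -> int:
        return self.samples[0][0]

    @property
    def t1(self) -> int:
        return self.samples[-1][0]

    @property
    def duration(self) -> int:
        return self.t1 - self.t0

    @property
    def start_pos(self) -> tuple[float, float]:
        return self.samples[0][1:]

    @property
    def end_pos(self) -> tuple[float, float]:
        return self.samples[-1][1:]

    @property
    def path_length(self) -> float:
        return sum(
            math.hypot(x1 - x0, y1 - y0)
            for (_, x0, y0), (_, x1, y1) in zip(self.samples, self.samples[1:])
        )

    @property
    def net_displacement(self) -> float:
        (x0, y0), (x1, y1) = self.start_pos, self.end_pos
        return math.hypot(x1 - x0, y1 - y0)

    def centroid(self) -> tuple[float, float]:
        xs = [s[1] for s in self.samples]
        ys = [s[2] for s in self.samples]
        return (sum(xs) / len(xs), sum(ys) / len(ys))

    def wander_radius(self) -> float:
        """Max distance of any sample from the stroke centroid."""
        cx, cy = self.centroid()
        return max(math.hypot(x - cx, y - cy) for _, x, y in self.samples)

    def bbox_diagonal(self) -> float:
        xs = [s[1] for s in self.samples]
        ys = [s[2] for s in self.samples]
        return math.hypot(max(xs) - min(xs), max(ys) - min(ys))

    def significant_points(self, min_move: float) -> list[tuple[float, float]]:
        """Samples thinned so consecutive points are >= min_move apart."""
        pts = [self.start_pos]
        for _, x, y in self.samples[1:]:
            if math.hypot(x - pts[-1][0], y - pts[-1][1]) >= min_move:
                pts.append((x, y))
        return pts

    def direction_reversals(self, min_move: float = 3.0, cos_thresh: float = -0.5) -> int:
        """Count of direction changes sharper than the cosine threshold
        between consecutive significant displacement vectors."""
        pts = self.significant_points(min_move)
        count = 0
        for (ax, ay), (bx, by), (cx, cy) in zip(pts, pts[1:], pts[2:]):
            ux, uy = bx - ax, by - ay
            vx, vy = cx - bx, cy - by
            nu, nv = math.hypot(ux, uy), math.hypot(vx, vy)
            if nu == 0 or nv == 0:
                continue
            if (ux * vx + uy * vy) / (nu * nv) < cos_thresh:
                count += 1
        return count

    def aoi_sequence(self, aois: AoiMap) -> list[AoiCell | None]:
        """Cells visited, consecutive duplicates removed (None = outside)."""
        seq: list[AoiCell | None] = []
        for _, x, y in self.samples:
            cell = assign_aoi(aois, (x, y))
            key = cell.name if cell else None
            if not seq or (seq[-1].name if seq[-1] else None) != key:
                seq.append(cell)
        return seq

    def speeds(self) -> list[tuple[int, float]]:
        """Per-sample (t, speed px/s) within the stroke."""
        out = []
        for (t0, x0, y0), (t1, x1, y1) in zip(self.samples, self.samples[1:]):
            if t1 > t0:
                out.append((t1, math.hypot(x1 - x0, y1 - y0) / (t1 - t0) * 1000.0))
        return out


def segment_strokes(rows: list[DigitStateRow]) -> list[Stroke]:
    """One stroke per DOWN..UP run per input ID.

    An ERROR (sensor overload) force-closes the stroke at its last sample;
    a stroke left open at the end of the log is closed at its last sample
    and flagged ``unclosed``.
    """
    open_strokes: dict[int, Stroke] = {}
    done: list[Stroke] = []
    for row in rows:
        for d in range(N_DIGITS):
            e = row.events[d]
            if e is None:
                continue
            pos = row.positions[d]
            if e == EVENT_DOWN:
                if d in open_strokes:  # missing UP; close defensively
                    s = open_strokes.pop(d)
                    s.unclosed = True
                    done.append(s)
                open_strokes[d] = Stroke(input_id=d, samples=[(row.t, *pos)])
            elif e in (EVENT_MOVE, EVENT_STAT):
                if d in open_strokes:
                    open_strokes[d].samples.append((row.t, *pos))
            elif e == EVENT_UP:
                if d in open_strokes:
                    s = open_strokes.pop(d)
                    s.samples.append((row.t, *pos))
                    done.append(s)
            elif e == EVENT_ERROR:
                if d in open_strokes:
                    s = open_strokes.pop(d)
                    s.overload_closed = True
                    done.append(s)
    for s in open_strokes.values():
        s.unclosed = True
        done.append(s)
    done.sort(key=lambda s: (s.t0, s.input_id))
    return done


def _outline_geometry(aois: AoiMap, cell: AoiCell | None):
    """Shapely boundary of the object outline, or the cell rectangle."""
    if cell is None:
        return None
    outline = aois.outlines.get(cell.object_name) if cell.object_name else None
    if outline:
        return LineString(list(outline) + [outline[0]])
    r = cell.rect
    return LineString([(r.x0, r.y0), (r.x1, r.y0), (r.x1, r.y1), (r.x0, r.y1), (r.x0, r.y0)])


def _perimeter_proximal(stroke: Stroke, boundary, tol: float) -> bool:
    if boundary is None:
        return False
    near = sum(boundary.distance(ShapelyPoint(x, y)) <= tol for _, x, y in stroke.samples)
    return near >= 0.8 * len(stroke.samples)


def _pauses(stroke: Stroke, params: RuleParams) -> list[tuple[int, int]]:
    """Contiguous (t_start, t_end) intervals with speed < pause_speed that
    last at least pause_min_ms."""
    out = []
    start = None
    prev_t = stroke.t0
    for t, v in stroke.speeds():
        if v < params.pause_speed:
            if start is None:
                start = prev_t
        else:
            if start is not None and prev_t - start >= params.pause_min_ms:
                out.append((start, prev_t))
            start = None
        prev_t = t
    if start is not None and prev_t - start >= params.pause_min_ms:
        out.append((start, prev_t))
    return out


def _is_ordered_traversal(cells: list[AoiCell]) -> bool:
    """True if the distinct-cell sequence walks a row or a column in order
    (monotone along one axis, constant on the other, steps of one cell)."""
    if len(cells) < 2:
        return False
    rows = [c.row for c in cells]
    cols = [c.col for c in cells]
    same_row = len(set(rows)) == 1
    same_col = len(set(cols)) == 1
    if same_row:
        steps = [b - a for a, b in zip(cols, cols[1:])]
    elif same_col:
        steps = [b - a for a, b in zip(rows, rows[1:])]
    else:
        return False
    return all(s == 1 for s in steps) or all(s == -1 for s in steps)


def classify_stroke(
    stroke: Stroke, aois: AoiMap, params: RuleParams = RuleParams()
) -> tuple[ActionLabel, float]:
    """Rule-based action label for one stroke, with a confidence in (0, 1].

    Rule order (fixed tie-break, deterministic given the parameters):
    single-AOI strokes — tap / fix (stationary touches, split on duration)
    before brush (>= 2 direction reversals) before trace (perimeter-
    proximal, no backtrack) before glance (fast full transit) before
    scan-within (one movement in any direction); multi-AOI strokes —
    slideTo (distinct endpoints, no intermediate pause) before scan
    (ordered row/column traversal) before skim (everything else).
    """
    if not stroke.samples:
        raise ValueError("cannot classify an empty stroke")
    seq = stroke.aoi_sequence(aois)
    distinct = []
    for cell in seq:
        if cell is not None and (not distinct or distinct[-1].name != cell.name):
            distinct.append(cell)
    reversals = stroke.direction_reversals(params.min_move, params.reversal_cos)
    stationary = stroke.wander_radius() <= params.stationary_radius

    if len({c.name for c in distinct}) <= 1:
        cell = distinct[0] if distinct else None
        if stationary:
            if stroke.duration < params.tap_max:
                return ActionLabel.TAP, 0.95
            if stroke.duration >= 500:
                return ActionLabel.FIX, 0.95
            # momentary-but-not-instant stationary touch: still a tap
            return ActionLabel.TAP, 0.6
        if reversals >= 2 and stroke.duration >= 500:
            return ActionLabel.BRUSH, 0.9
        boundary = _outline_geometry(aois, cell)
        if (
            reversals == 0
            and stroke.path_length >= 2 * params.stationary_radius
            and _perimeter_proximal(stroke, boundary, params.perimeter_tol)
        ):
            return ActionLabel.TRACE, 0.9
        speeds = [v for _, v in stroke.speeds()]
        no_pause = bool(speeds) and min(speeds) >= params.pause_speed
        cell_size = min(cell.rect.width, cell.rect.height) if cell else float("inf")
        transit = stroke.net_displacement >= params.glance_transit_frac * cell_size
        if no_pause and transit and stroke.duration < 500:
            return ActionLabel.GLANCE, 0.7
        if stroke.duration < 500:
            return ActionLabel.SCAN_WITHIN, 0.7
        if reversals >= 1:
            return ActionLabel.BRUSH, 0.5
        return ActionLabel.TRACE, 0.4

    # multi-AOI
    pauses = _pauses(stroke, params)
    start_cell, end_cell = distinct[0], distinct[-1]
    intermediate = {c.name for c in distinct[1:-1]}

    def _in_intermediate(t: int) -> bool:
        for ts, x, y in stroke.samples:
            if ts >= t:
                cell = assign_aoi(aois, (x, y))
                return cell is not None and cell.name in intermediate
        return False

    intermediate_pause = any(_in_intermediate(ts) for ts, _ in pauses)
    if start_cell.name != end_cell.name and not intermediate_pause and stroke.duration < 2000:
        if len(distinct) <= 2 or not _is_ordered_traversal(distinct):
            return ActionLabel.SLIDE_TO, 0.85
    if _is_ordered_traversal(distinct):
        return ActionLabel.SCAN, 0.8
    return ActionLabel.SKIM, 0.6


@dataclass(frozen=True)
class InterStrokeEvent:
    """An off-surface interval between consecutive strokes of one ID."""

    input_id: int
    t_start: int
    duration: int
    label: ActionLabel | None  # None = park/break candidate, indeterminate
    note: str = ""

    @property
    def t_end(self) -> int:
        return self.t_start + self.duration


def detect_inter_stroke(
    strokes: list[Stroke], aois: AoiMap, params: RuleParams = RuleParams()
) -> list[InterStrokeEvent]:
    """Classify the gaps between consecutive strokes of each input ID.

    Lift-off and return to the same object after >= 500 ms with no
    intervening translation is a hover; lift-off landing in a different
    AOI within ``jump_max`` is a jumpTo.  Longer gaps can only be flagged
    as park/break candidates: off-surface positions are not captured by
    the logger, so the two cannot be distinguished from the log alone.
    """
    events: list[InterStrokeEvent] = []
    by_id: dict[int, list[Stroke]] = {}
    for s in strokes:
        by_id.setdefault(s.input_id, []).append(s)
    for d, ss in sorted(by_id.items()):
        ss = sorted(ss, key=lambda s: s.t0)
        for a, b in zip(ss, ss[1:]):
            gap = b.t0 - a.t1
            if gap <= 0:
                continue
            cell_a = assign_aoi(aois, a.end_pos)
            cell_b = assign_aoi(aois, b.start_pos)
            same = cell_a is not None and cell_b is not None and cell_a.name == cell_b.name
            translation = math.hypot(
                b.start_pos[0] - a.end_pos[0], b.start_pos[1] - a.end_pos[1]
            )
            if same and gap >= params.hover_min and translation <= 2 * params.stationary_radius:
                events.append(InterStrokeEvent(d, a.t1, gap, ActionLabel.HOVER))
            elif not same and gap < params.jump_max:
                events.append(InterStrokeEvent(d, a.t1, gap, ActionLabel.JUMP_TO))
            elif gap >= params.offsurface_min:
                events.append(
                    InterStrokeEvent(
                        d, a.t1, gap, None, note="park/break candidate; unobservable from log"
                    )
                )
    events.sort(key=lambda e: e.t_start)
    return events


@dataclass(frozen=True)
class SpanEvent:
    """One digit anchored while another stretches to a new location."""

    anchor_id: int
    mover_id: int
    t_start: int
    duration: int

    @property
    def t_end(self) -> int:
        return self.t_start + self.duration


def detect_span(
    strokes: list[Stroke], aois: AoiMap, params: RuleParams = RuleParams()
) -> list[SpanEvent]:
    """Detect spans: a stationary anchor stroke in one AOI while a
    temporally overlapping stroke starts near the anchor (within the
    hand-radius cluster distance) and ends in a different AOI."""
    spans = []
    for anchor in strokes:
        if anchor.wander_radius() > params.stationary_radius:
            continue
        cell_a = assign_aoi(aois, anchor.centroid())
        for mover in strokes:
            if mover is anchor or mover.input_id == anchor.input_id:
                continue
            if mover.t0 < anchor.t0 or mover.t0 > anchor.t1:
                continue  # must start during the anchor's contact
            ax, ay = anchor.centroid()
            sx, sy = mover.start_pos
            if math.hypot(sx - ax, sy - ay) > params.hand_radius:
                continue
            cell_m = assign_aoi(aois, mover.end_pos)
            if cell_m is None or (cell_a is not None and cell_m.name == cell_a.name):
                continue
            spans.append(SpanEvent(anchor.input_id, mover.input_id, mover.t0, mover.duration))
    spans.sort(key=lambda s: s.t_start)
    return spans


@dataclass
class GestureCode:
    """One protocol line (first-pass or detailed).

    ``location`` is one or more 1-based (row, col) grid locations;
    ``object_name`` one or more object names joined with '+'.  By naming
    convention target-pair objects are fully capitalized and distractors
    mixed case.  Levels: 1 = whole shape, 2 = part of a shape,
    3 = individual sides/corners.  ``fingers`` patterns like ``R12(T)``
    are import-only fields for video-coded protocols.
    """

    time: int
    hand: Hand = Hand.UNKNOWN
    fingers: str = ""
    action: ActionLabel | None = None
    duration: int | None = None
    location: tuple[tuple[int, int], ...] = ()
    object_name: str = ""
    level: int = 1
    comment: str = ""
    coding_pass: str = "first_pass"  # or "detailed"

    @property
    def t_end(self) -> int:
        return self.time + (self.duration or 0)


def _occupancy(row: DigitStateRow, aois: AoiMap) -> frozenset[tuple[str, tuple[int, int]]]:
    occ = set()
    for d in row.digits_in_use():
        cell = assign_aoi(aois, row.positions[d])
        if cell is not None:
            occ.add((cell.object_name or cell.name, cell.location))
    return frozenset(occ)


def first_pass_coding(rows: list[DigitStateRow], aois: AoiMap) -> list[GestureCode]:
    """Segment the trial into intervals of constant AOI occupancy.

    A new line is generated whenever the set of occupied (object,
    location) pairs changes — including to the empty set, as when both
    hands are briefly lifted.  Multi-AOI lines carry all the objects and a
    range of locations.
    """
    codes: list[GestureCode] = []
    current: frozenset | None = None
    start_t: int | None = None
    for row in rows:
        occ = _occupancy(row, aois)
        if current is None or occ != current:
            if current is not None:
                codes.append(_occupancy_code(start_t, row.t - start_t, current))
            current, start_t = occ, row.t
    if current is not None:
        end_t = rows[-1].t
        # a zero-length empty line at the trial's final lift-off is not a
        # segment, just the end of the protocol
        if current or end_t > start_t:
            codes.append(_occupancy_code(start_t, end_t - start_t, current))
    return codes


def _occupancy_code(t: int, duration: int, occ: frozenset) -> GestureCode:
    items = sorted(occ, key=lambda it: it[1])
    return GestureCode(
        time=t,
        duration=duration,
        object_name="+".join(name for name, _ in items),
        location=tuple(loc for _, loc in items),
        level=1,
        coding_pass="first_pass",
    )


def _assign_level(stroke: Stroke, aois: AoiMap, cell: AoiCell | None, params: RuleParams) -> int:
    """Level from the spatial extent of the action relative to the object:
    below 25% of the object's bounding diagonal is level 3 (a side or
    corner), below 75% level 2 (part of the shape), else level 1."""
    if cell is None:
        return 1
    outline = aois.outlines.get(cell.object_name) if cell.object_name else None
    if outline:
        xs = [p[0] for p in outline]
        ys = [p[1] for p in outline]
        ref = math.hypot(max(xs) - min(xs), max(ys) - min(ys))
    else:
        ref = math.hypot(cell.rect.width, cell.rect.height)
    frac = stroke.bbox_diagonal() / ref if ref > 0 else 0.0
    if frac < params.level3_frac:
        return 3
    if frac < params.level2_frac:
        return 2
    return 1


def _stroke_code(stroke: Stroke, aois: AoiMap, params: RuleParams) -> GestureCode:
    label, conf = classify_stroke(stroke, aois, params)
    seq = [c for c in stroke.aoi_sequence(aois) if c is not None]
    locs: list[tuple[int, int]] = []
    for c in seq:
        if c.location not in locs:
            locs.append(c.location)
    majority = seq[0] if seq else None
    return GestureCode(
        time=stroke.t0,
        action=label,
        duration=stroke.duration,
        location=tuple(locs),
        object_name="+".join(dict.fromkeys(c.object_name or c.name for c in seq)),
        level=_assign_level(stroke, aois, majority, params),
        comment=f"confidence={conf:.2f}",
        coding_pass="detailed",
    )


def detailed_coding(
    rows: list[DigitStateRow],
    aois: AoiMap,
    selection: list[tuple[int, int]],
    first_pass: list[GestureCode] | None = None,
    params: RuleParams = RuleParams(),
) -> list[GestureCode]:
    """Elementary-action codes within selected time ranges, nested under
    the first-pass lines.

    Codes are clipped to their parent first-pass line's interval; when an
    action persists across a line boundary the continuation code carries
    the ``//`` ("gesture continues as above") comment.
    """
    if not rows:
        raise ValueError("no rows to code")
    span = (rows[0].t, rows[-1].t)
    for lo, hi in selection:
        if hi < lo or hi < span[0] or lo > span[1]:
            raise ValueError(f"selection ({lo}, {hi}) outside trial span {span}")
    if first_pass is None:
        first_pass = first_pass_coding(rows, aois)
    strokes = segment_strokes(rows)
    codes: list[GestureCode] = []
    for stroke in strokes:
        if not any(stroke.t0 <= hi and stroke.t1 >= lo for lo, hi in selection):
            continue
        code = _stroke_code(stroke, aois, params)
        codes.extend(_nest_under(code, first_pass))
    # inter-stroke and span events within the selection
    inter = detect_inter_stroke(strokes, aois, params)
    for ev in inter:
        if ev.label is None:
            continue
        if any(ev.t_start <= hi and ev.t_end >= lo for lo, hi in selection):
            code = GestureCode(
                time=ev.t_start, action=ev.label, duration=ev.duration,
                coding_pass="detailed", level=1,
            )
            codes.extend(_nest_under(code, first_pass))
    codes.sort(key=lambda c: c.time)
    return codes


def _nest_under(code: GestureCode, first_pass: list[GestureCode]) -> list[GestureCode]:
    """Clip a detailed code to the first-pass lines it overlaps; pieces
    after the first carry the '//' continuation comment."""
    if not first_pass:
        return [code]
    pieces: list[GestureCode] = []
    for line in first_pass:
        lo = max(code.time, line.time)
        hi = min(code.t_end, line.t_end)
        if hi <= lo and not (code.duration == 0 and line.time <= code.time < line.t_end):
            continue
        piece = replace(code, time=lo, duration=max(hi - lo, 0))
        if pieces:
            piece.comment = ("// " + piece.comment).strip()
        pieces.append(piece)
    return pieces or [code]


def auto_code(
    rows: list[DigitStateRow], aois: AoiMap, params: RuleParams = RuleParams()
) -> list[GestureCode]:
    """Fully automatic elementary-action coding of a whole trial.

    Returns stroke labels, inter-stroke events (hover/jumpTo and
    indeterminate off-surface candidates) and span events as a flat,
    time-ordered list of detailed codes with hand=unknown.
    """
    strokes = segment_strokes(rows)
    codes = [_stroke_code(s, aois, params) for s in strokes]
    for ev in detect_inter_stroke(strokes, aois, params):
        codes.append(
            GestureCode(
                time=ev.t_start,
                action=ev.label,
                duration=ev.duration,
                comment=ev.note,
                coding_pass="detailed",
            )
        )
    for sp in detect_span(strokes, aois, params):
        codes.append(
            GestureCode(
                time=sp.t_start,
                action=ActionLabel.SPAN,
                duration=sp.duration,
                comment=f"anchor={sp.anchor_id} mover={sp.mover_id}",
                coding_pass="detailed",
            )
        )
    codes.sort(key=lambda c: c.time)
    return codes


def gesture_time_budget(
    codes: list[GestureCode],
    window: tuple[int, int] | None = None,
    per_hand: bool = False,
) -> dict:
    """Proportion of coded time spent on each action label.

    Durations are clipped to the window and normalized by the total coded
    time within it; with ``per_hand`` the keys are (hand, label) pairs.
    """
    totals: dict = {}
    for code in codes:
        if code.action is None or code.duration is None:
            continue
        lo, hi = code.time, code.t_end
        if window is not None:
            lo, hi = max(lo, window[0]), min(hi, window[1])
        if hi <= lo:
            continue
        key = (code.hand, code.action) if per_hand else code.action
        totals[key] = totals.get(key, 0) + (hi - lo)
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {k: v / grand for k, v in totals.items()}


def mins_secs(ms: int) -> str:
    """Human-readable minutes:seconds, e.g. 78,000 ms -> '1:18'."""
    return f"{ms // 60000}:{(ms % 60000) // 1000:02d}"


_COLUMNS = [
    "Timestamp", "MinsSecs", "Pass", "Hand", "Fingers", "Action",
    "DurationMs", "Location", "Object", "Level", "Comment",
]


def _fmt_locations(locs: tuple[tuple[int, int], ...]) -> str:
    return "+".join(f"[{r},{c}]" for r, c in locs)


def _parse_locations(text: str) -> tuple[tuple[int, int], ...]:
    if not text:
        return ()
    out = []
    for part in text.split("+"):
        r, c = part.strip("[]").split(",")
        out.append((int(r), int(c)))
    return tuple(out)


def export_coding(codes: list[GestureCode]) -> str:
    """Serialize codes to a TSV coding sheet (round-trips on machine
    fields; MinsSecs is derived for human readers)."""
    lines = ["\t".join(_COLUMNS)]
    for code in codes:
        lines.append(
            "\t".join(
                [
                    str(code.time),
                    mins_secs(code.time),
                    code.coding_pass,
                    code.hand.value,
                    code.fingers,
                    code.action.value if code.action else "",
                    "" if code.duration is None else str(code.duration),
                    _fmt_locations(code.location),
                    code.object_name,
                    str(code.level),
                    code.comment,
                ]
            )
        )
    return "\n".join(lines) + "\n"


def import_coding(text: str) -> list[GestureCode]:
    """Parse a TSV coding sheet back into codes."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    if header != _COLUMNS:
        raise ValueError(f"line 1: unexpected header {header!r}")
    codes = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(_COLUMNS):
            raise ValueError(
                f"line {lineno}: expected {len(_COLUMNS)} tab-separated fields, got {len(fields)}"
            )
        (ts, _ms, cpass, hand, fingers, action, dur, loc, obj, level, comment) = fields
        codes.append(
            GestureCode(
                time=int(ts),
                hand=Hand(hand),
                fingers=fingers,
                action=ActionLabel(action) if action else None,
                duration=int(dur) if dur else None,
                location=_parse_locations(loc),
                object_name=obj,
                level=int(level),
                comment=comment,
                coding_pass=cpass,
            )
        )
    return codes
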