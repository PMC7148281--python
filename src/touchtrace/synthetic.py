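"""Ground-truth synthetic touch streams in the raw logger format.

Scripts of gesture primitives (trace, fix, tap, brush, glance,
scan-within, slideTo, jumpTo, skim, scan, hover, span) are rendered into
event logs sampled at a configurable rate (default 60 Hz, emulating the
screen refresh cadence of capacitive tablets) with per-axis Gaussian
positional jitter, a four-corner calibration header, up to ten concurrent
digit slots, and optional sensor-overload injection.  Each rendered log is
paired with truth labels (start, end, digit, label, object) so classifier
output can be scored against what was scripted.

The generator aims at geometric/kinematic realism only — it does not
simulate search strategies or memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import AoiMap, Rect, make_grid_aois
from .log_io import Action, CalibrationTouch, TouchEvent, TouchLog
from .tpa_coding import ActionLabel, GestureCode

__all__ = [
    "ShapeSpec",
    "SyntheticStimulus",
    "Primitive",
    "TruthRecord",
    "make_stimulus",
    "render_script",
    "inject_overload",
    "build_demo_script",
    "write_truth",
    "recovery_score",
]

Point = tuple[float, float]

#: labels whose recovery the scripted corpus is designed to exercise
CORE_LABELS = ("trace", "fix", "tap", "brush", "slide_to", "jump_to", "hover", "span")


def _regular_polygon(center: Point, radius: float, n: int, phase: float = -math.pi / 2) -> list[Point]:
    return [
        (center[0] + radius * math.cos(phase + 2 * math.pi * k / n),
         center[1] + radius * math.sin(phase + 2 * math.pi * k / n))
        for k in range(n)
    ]


def _square(center: Point, half: float) -> list[Point]:
    cx, cy = center
    return [(cx - half, cy - half), (cx + half, cy - half), (cx + half, cy + half), (cx - half, cy + half)]


_SHAPE_BUILDERS = {
    "square": lambda c, r: _square(c, r / math.sqrt(2)),
    "triangle": lambda c, r: _regular_polygon(c, r, 3),
    "pentagon": lambda c, r: _regular_polygon(c, r, 5),
    "hexagon": lambda c, r: _regular_polygon(c, r, 6),
    "circle": lambda c, r: _regular_polygon(c, r, 16),
    "diamond": lambda c, r: _regular_polygon(c, r, 4, phase=0.0),
}


@dataclass(frozen=True)
class ShapeSpec:
    """One object: shape kind, name, and role (target pair / distractor).

    Target-pair names are fully capitalized; distractors mixed case.
    """

    kind: str
    name: str
    is_target: bool = True


#: the default 3x3 layout: three matching pairs plus three distractors
DEFAULT_SHAPES = [
    ShapeSpec("square", "SQUARE-A"),
    ShapeSpec("triangle", "TRIANGLE-A"),
    ShapeSpec("circle", "Circle-a", is_target=False),
    ShapeSpec("pentagon", "PENTAGON-A"),
    ShapeSpec("square", "SQUARE-B"),
    ShapeSpec("hexagon", "Hexagon-a", is_target=False),
    ShapeSpec("triangle", "TRIANGLE-B"),
    ShapeSpec("diamond", "Diamond-a", is_target=False),
    ShapeSpec("pentagon", "PENTAGON-B"),
]


@dataclass
class SyntheticStimulus:
    """Capture-area bounds, grid shape, and named object outlines."""

    bounds: Rect
    rows: int
    cols: int
    shapes: list[ShapeSpec]
    outlines: dict[str, list[Point]] = field(default_factory=dict)

    def centroid(self, name: str) -> Point:
        pts = self.outlines[name]
        return (sum(p[0] for p in pts) / len(pts), sum(p[1] for p in pts) / len(pts))


def make_stimulus(
    rows: int = 3,
    cols: int = 3,
    shapes: list[ShapeSpec] | None = None,
    bounds: Rect = Rect(0, 0, 900, 900),
    shape_frac: float = 0.6,
    seed: int = 0,
) -> tuple[SyntheticStimulus, AoiMap]:
    """Deterministic stimulus: one named shape centred in each grid cell.

    ``shape_frac`` sets the shape diameter as a fraction of the smaller
    cell dimension; fractions >= 1 would spill outside the cell and raise.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if shapes is None:
        shapes = [DEFAULT_SHAPES[i % len(DEFAULT_SHAPES)] for i in range(rows * cols)]
    if len(shapes) != rows * cols:
        raise ValueError(f"expected {rows * cols} shapes, got {len(shapes)}")
    if shape_frac >= 1.0:
        raise ValueError("shapes too large for cells (shape_frac must be < 1)")
    aois = make_grid_aois(bounds, rows, cols, object_names=[s.name for s in shapes])
    outlines: dict[str, list[Point]] = {}
    for cell, spec in zip(aois.cells, shapes):
        radius = shape_frac * min(cell.rect.width, cell.rect.height) / 2
        outlines[spec.name] = _SHAPE_BUILDERS[spec.kind](cell.rect.center(), radius)
    stim = SyntheticStimulus(bounds=bounds, rows=rows, cols=cols, shapes=shapes, outlines=outlines)
    aois.outlines = outlines
    return stim, aois


@dataclass(frozen=True)
class Primitive:
    """One scripted gesture on one digit slot.

    ``jump_to`` and ``hover`` are gap annotations: they emit no samples
    and label the off-surface interval between the surrounding contacts.
    ``span`` occupies two slots (``digit`` anchors, ``digit2`` stretches).
    """

    kind: str
    targets: tuple[str, ...]
    start: int
    duration: int
    digit: int = 0
    digit2: int | None = None
    n_passes: int = 4  # brush half-passes
    fraction: float = 1.0  # portion of the outline a trace covers


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for one scripted interval."""

    t_start: int
    t_end: int
    digit: int
    label: str
    object_name: str

    @property
    def duration(self) -> int:
        return self.t_end - self.t_start


def _polyline_path(points: list[Point]):
    """Constant-speed parametrisation u in [0,1] along a polyline."""
    seglens = [math.hypot(b[0] - a[0], b[1] - a[1]) for a, b in zip(points, points[1:])]
    total = sum(seglens)
    if total == 0:
        return lambda u: points[0]

    def path(u: float) -> Point:
        d = u * total
        for (a, b), L in zip(zip(points, points[1:]), seglens):
            if d <= L or L == seglens[-1] and (a, b) == (points[-2], points[-1]):
                if L == 0:
                    return a
                f = min(d / L, 1.0)
                return (a[0] + f * (b[0] - a[0]), a[1] + f * (b[1] - a[1]))
            d -= L
        return points[-1]

    return path


def _primitive_contacts(p: Primitive, stim: SyntheticStimulus) -> list[tuple[int, int, int, object]]:
    """Expand a primitive into (digit_slot, t0, t1, path) contacts."""
    if p.kind in ("jump_to", "hover"):
        return []
    if p.kind == "fix" or p.kind == "tap":
        pt = stim.centroid(p.targets[0])
        return [(p.digit, p.start, p.start + p.duration, lambda u, pt=pt: pt)]
    if p.kind == "trace":
        outline = stim.outlines[p.targets[0]]
        closed = list(outline) + [outline[0]]
        if p.fraction < 1.0:
            path_full = _polyline_path(closed)
            pts = [path_full(u * p.fraction) for u in np.linspace(0, 1, 40)]
        else:
            pts = closed
        return [(p.digit, p.start, p.start + p.duration, _polyline_path(pts))]
    if p.kind == "brush":
        outline = stim.outlines[p.targets[0]]
        a, b = outline[0], outline[1]
        pts = [a if i % 2 == 0 else b for i in range(p.n_passes + 1)]
        return [(p.digit, p.start, p.start + p.duration, _polyline_path(pts))]
    if p.kind == "glance":
        cx, cy = stim.centroid(p.targets[0])
        xs = [pt[0] for pt in stim.outlines[p.targets[0]]]
        half = 0.7 * (max(xs) - min(xs))
        return [(p.digit, p.start, p.start + p.duration,
                 _polyline_path([(cx - half, cy), (cx + half, cy)]))]
    if p.kind == "scan_within":
        cx, cy = stim.centroid(p.targets[0])
        xs = [pt[0] for pt in stim.outlines[p.targets[0]]]
        r = 0.3 * (max(xs) - min(xs))
        return [(p.digit, p.start, p.start + p.duration, _polyline_path([(cx - r, cy), (cx + r, cy)]))]
    if p.kind == "slide_to":
        a = stim.centroid(p.targets[0])
        b = stim.centroid(p.targets[1])
        return [(p.digit, p.start, p.start + p.duration, _polyline_path([a, b]))]
    if p.kind in ("skim", "scan"):
        pts = [stim.centroid(name) for name in p.targets]
        if p.kind == "scan":
            # dwell briefly at each object so intermediate pauses are real
            dwell: list[Point] = []
            for pt in pts:
                dwell += [pt, pt]
            pts = dwell
        return [(p.digit, p.start, p.start + p.duration, _polyline_path(pts))]
    if p.kind == "span":
        if p.digit2 is None:
            raise ValueError("span needs two digit slots")
        anchor = stim.centroid(p.targets[0])
        target = stim.centroid(p.targets[1])
        start_near = (anchor[0] + 40.0, anchor[1])
        mover_t0 = p.start + 100
        return [
            (p.digit, p.start, p.start + p.duration, lambda u, pt=anchor: pt),
            (p.digit2, mover_t0, p.start + p.duration, _polyline_path([start_near, target])),
        ]
    raise ValueError(f"unknown primitive kind {p.kind!r}")


def _truth(p: Primitive, stim: SyntheticStimulus) -> TruthRecord:
    obj = "+".join(p.targets)
    digit = p.digit2 if p.kind == "span" and p.digit2 is not None else p.digit
    return TruthRecord(p.start, p.start + p.duration, digit, p.kind, obj)


def render_script(
    script: list[Primitive],
    stimulus: SyntheticStimulus,
    rate_hz: float = 60.0,
    jitter_sigma: float = 0.0,
    seed: int = 0,
    time_jitter_ms: int = 0,
) -> tuple[TouchLog, list[TruthRecord]]:
    """Render a gesture script into a raw touch log plus truth labels.

    Events are sampled at ``rate_hz`` along each primitive's path with
    per-axis Gaussian positional jitter (standard deviation
    ``jitter_sigma`` pixels, seeded).  Each contact is framed
    DOWN, MOVE*, UP.  Input IDs mimic the logger: the lowest free integer
    0-9 is taken at DOWN and held until UP.  Timestamp jitter is off by
    default (fixed cadence); ``time_jitter_ms`` adds uniform +/- jitter to
    emulate device scheduling.  A four-corner calibration header
    (top-left, top-right, bottom-left, bottom-right) is included.
    """
    rng = np.random.default_rng(seed)
    contacts: list[tuple[int, int, int, object]] = []
    for p in script:
        contacts.extend(_primitive_contacts(p, stimulus))
    # per digit slot, contacts must not overlap in time
    by_slot: dict[int, list[tuple[int, int]]] = {}
    for slot, t0, t1, _ in contacts:
        for a, b in by_slot.get(slot, []):
            if t0 < b and t1 > a:
                raise ValueError(f"primitives collide on digit slot {slot}: ({t0},{t1}) vs ({a},{b})")
        by_slot.setdefault(slot, []).append((t0, t1))

    contacts.sort(key=lambda c: c[0:2] and (c[1], c[0]))
    # assign input IDs: lowest free 0-9 at DOWN, freed at UP
    active: dict[int, int] = {}  # input id -> release time
    events: list[TouchEvent] = []
    for slot, t0, t1, path in contacts:
        for ident, until in list(active.items()):
            if until <= t0:
                del active[ident]
        free = [i for i in range(10) if i not in active]
        if not free:
            raise ValueError(f"more than ten concurrent contacts at t={t0}")
        ident = free[0]
        active[ident] = t1
        n = max(2, int(round((t1 - t0) * rate_hz / 1000.0)) + 1)
        for i in range(n):
            t = t0 + int(round(i * (t1 - t0) / (n - 1)))
            if time_jitter_ms and 0 < i < n - 1:
                t += int(rng.integers(-time_jitter_ms, time_jitter_ms + 1))
            x, y = path(i / (n - 1))
            if jitter_sigma > 0:
                x += rng.normal(0.0, jitter_sigma)
                y += rng.normal(0.0, jitter_sigma)
            action = Action.DOWN if i == 0 else Action.UP if i == n - 1 else Action.MOVE
            events.append(TouchEvent(ident, x, y, t, action))
    events.sort(key=lambda e: e.t)  # stable: preserves per-contact order

    b = stimulus.bounds
    calibration = [
        CalibrationTouch(i, x, y, t=100 * i, corner_label=label)
        for i, ((x, y), label) in enumerate(
            zip(b.corners(), ("top-left", "top-right", "bottom-left", "bottom-right"))
        )
    ]
    log = TouchLog(
        calibration=calibration,
        events=events,
        meta={"generator": "touchtrace.synthetic", "rate_hz": str(rate_hz), "seed": str(seed)},
    )
    truth = sorted((_truth(p, stimulus) for p in script), key=lambda r: r.t_start)
    return log, truth


def inject_overload(log: TouchLog, at: int, duration: int) -> TouchLog:
    """Insert a sensor-overload event at ``at`` and re-establish contacts.

    Contacts active at ``at`` are force-closed (their samples inside
    ``[at, at + duration)`` are dropped); they resume at ``at + duration``
    from their scheduled positions with freshly assigned IDs, emulating a
    participant briefly lifting their hands in response to the overload
    warning.
    """
    if log.events and not (log.events[0].t <= at <= log.events[-1].t):
        raise ValueError("overload time outside log span")
    resume = at + duration
    # split events into per-contact runs to find contacts straddling `at`
    runs: list[list[TouchEvent]] = []
    open_runs: dict[int, list[TouchEvent]] = {}
    for ev in log.events:
        if ev.action is Action.DOWN:
            open_runs[ev.input_id] = [ev]
            runs.append(open_runs[ev.input_id])
        elif ev.action in (Action.MOVE, Action.UP):
            open_runs.get(ev.input_id, []).append(ev)
        else:
            runs.append([ev])
    new_events: list[TouchEvent] = [TouchEvent(-1, 0.0, 0.0, at, Action.OVERLOAD)]
    used: list[tuple[int, int, int]] = []  # (input_id, t0, t1) of kept runs
    resumed: list[list[TouchEvent]] = []
    for run in runs:
        t0, t1 = run[0].t, run[-1].t
        if t0 <= at <= t1:  # straddles the overload: truncate + resume
            kept = [ev for ev in run if ev.t < at]
            new_events.extend(kept)
            if kept:
                used.append((run[0].input_id, t0, at))
            tail = [ev for ev in run if ev.t >= resume]
            if tail:
                resumed.append(tail)
        else:
            new_events.extend(run)
            if run[0].action is not Action.OVERLOAD:
                used.append((run[0].input_id, t0, t1))
    for tail in sorted(resumed, key=lambda r: r[0].t):
        t0, t1 = tail[0].t, tail[-1].t
        taken = {i for i, a, b in used if a < t1 and b > t0}
        free = [i for i in range(10) if i not in taken]
        ident = free[0] if free else tail[0].input_id
        used.append((ident, t0, t1))
        fixed = [TouchEvent(ident, tail[0].x, tail[0].y, tail[0].t, Action.DOWN)]
        fixed += [TouchEvent(ident, ev.x, ev.y, ev.t, ev.action) for ev in tail[1:]]
        if len(fixed) == 1:  # a lone sample still needs closing
            fixed.append(TouchEvent(ident, tail[0].x, tail[0].y, tail[0].t + 1, Action.UP))
        new_events.extend(fixed)
    new_events.sort(key=lambda e: e.t)
    return TouchLog(calibration=list(log.calibration), events=new_events, meta=dict(log.meta))


def build_demo_script(stim: SyntheticStimulus, repeats: int = 2) -> list[Primitive]:
    """A deterministic corpus exercising the core recoverable labels.

    Primitives are sequenced on one digit slot with 1,500 ms inter-gesture
    gaps (too long for a jumpTo, too short for an off-surface candidate),
    except hover/jumpTo gaps and the two-slot span; durations sit inside
    each label's admissible time-scale class.
    """
    names = [s.name for s in stim.shapes]
    if len(names) < 4:
        raise ValueError("need a stimulus with at least 4 objects")
    script: list[Primitive] = []
    t = 1000
    gap = 1500
    for r in range(repeats):
        a, b, c, d = (names[(2 * r + k) % len(names)] for k in range(4))
        script.append(Primitive("trace", (a,), t, 1200)); t += 1200 + gap
        script.append(Primitive("fix", (b,), t, 1000)); t += 1000 + gap
        script.append(Primitive("tap", (c,), t, 80)); t += 80 + gap
        script.append(Primitive("brush", (d,), t, 1000)); t += 1000 + gap
        script.append(Primitive("slide_to", (a, b), t, 450)); t += 450 + gap
        # jumpTo: fix at c, 250 ms airborne, fix at d
        script.append(Primitive("fix", (c,), t, 700))
        script.append(Primitive("jump_to", (c, d), t + 700, 250))
        script.append(Primitive("fix", (d,), t + 950, 700)); t += 1650 + gap
        # hover: lift and return to the same object, no translation
        script.append(Primitive("fix", (a,), t, 700))
        script.append(Primitive("hover", (a,), t + 700, 900))
        script.append(Primitive("fix", (a,), t + 1600, 700)); t += 2300 + gap
        script.append(Primitive("span", (b, c), t, 550, digit=0, digit2=1)); t += 550 + gap
    return script


def write_truth(truth: list[TruthRecord]) -> str:
    """Serialize truth labels as TSV."""
    lines = ["t_start\tt_end\tdigit\tlabel\tobject"]
    for r in truth:
        lines.append(f"{r.t_start}\t{r.t_end}\t{r.digit}\t{r.label}\t{r.object_name}")
    return "\n".join(lines) + "\n"


def recovery_score(
    truth: list[TruthRecord],
    codes: list[GestureCode],
    labels: tuple[str, ...] = CORE_LABELS,
) -> float:
    """Fraction of truth intervals recovered by the automatic coding.

    A truth record counts as recovered when some code carries the same
    action label and overlaps at least half of the truth interval.
    """
    relevant = [r for r in truth if r.label in labels]
    if not relevant:
        return float("nan")
    hits = 0
    for r in relevant:
        want = ActionLabel(r.label)
        for code in codes:
            if code.action is not want or code.duration is None:
                continue
            overlap = min(r.t_end, code.t_end) - max(r.t_start, code.time)
            if overlap >= 0.5 * max(r.duration, 1):
                hits += 1
                break
    return hits / len(relevant)
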