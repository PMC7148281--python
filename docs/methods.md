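# Methods

## The data path

A capacitive-tablet logger records touch contacts through a tactile
graphic laid over the screen. Each recorded state is a quintuple
`InputID,locationX,locationY,timeStamp,touchAction` (device pixels,
integer milliseconds; action codes UP=0, DOWN=1, MOVE=2, overload=−1,
calibration=`*`). The screen refresh gives an average sampling cadence
of ~60 Hz (mean inter-event interval ≤ 17 ms), so a 5-minute trial can
yield up to `floor(300 s × 60 Hz) = 18,000` states per digit and 180,000
for ten digits in simultaneous use. IDs 0–9 are assigned to contacts in
order (lowest free integer at DOWN, held until UP): colour/ID encodes
contact order, never finger identity.

`touchtrace` processes such logs in stages: parse → calibrate →
digit-state table → kinematic/AOI measures → replay frames → gesture
coding. Each stage is a pure function over the previous stage's output,
so every intermediate product can be exported and inspected.

### Calibration model

The experimenter touches four marks at the corners of the stimulus; the
analyser aligns device coordinates to the stimulus by *offsets and
scaling only*. We therefore fit an axis-aligned per-axis model
`target = a·device + b` by ordinary least squares over the four
correspondences and expose it as `p′ = (p − offset)·scale` with
`scale = a`, `offset = −b/a`. No rotation or shear is fitted — the paper
sheet is affixed square to the screen — but per-corner residuals are
reported so a rotated or creased sheet is detectable (typical placement
error is 1–2 mm, which at ~3.5 px/mm corresponds to the default residual
tolerance users should expect). Fitting from all four corners rather
than two is a deliberate choice: it is what makes the residual report
meaningful.

### Digit-state table

Rows are *event-driven*: one row per distinct raw event timestamp (no
fixed-rate resampling — "no event, no data"). Digits in contact without
an event in that row are synthesized as STAT (code 3) at their last
known position, making the state of all ten potential inputs explicit. A
sensor-overload event (too large a touched area; the participant lifts
both hands briefly) marks every in-contact digit ERROR (−1) and
force-closes its contact segment. Events landing on the same millisecond
share a row; raw events 1–2 ms apart within one ~17 ms hardware frame
are *not* merged. A uniform-Δt resampling helper is provided for
histogramming but is clearly a derived view, not part of the dialect.

### Kinematics

Speed of a touch is the Euclidean distance between a digit's positions
in consecutive records of one contact segment, divided by the elapsed
time (px/s). The first sample of a segment has no predecessor, so its
speed is *undefined and omitted*, not zero. Per-record summaries take
the mean and max over defined speeds (single digit ⇒ mean = max; one
stationary + one moving ⇒ mean = max/2). Concurrency and dwell measures
weight each record by the forward interval to the next record (the last
record weighs zero); a record-count weighting is available by flag, since
published speed histograms count records. Dwell proportions default to
the *any-digit* rule — every AOI occupied by any in-contact digit
accrues the full interval, so proportions may sum to more than 1 — with
a *primary-digit* (lowest active ID) alternative; digit identity is
unknowable from the log, so neither rule can be per-finger.

### Replay frames and video timing

A frame is the half-open window `(t_end − trail, t_end]` — the labelled
end time is inclusive. Stepping by `step < trail` shares
`trail − step` ms between successive frames (1,000/1,200 → 200 ms;
2,000/2,400 → 400 ms). Rendering returns plot-ready dots (stimulus
coordinates + palette index = ID mod 10); the raster backend is
pluggable so tests stay image-free. Video is never decoded: the mapping
`frame = floor((t − offset)·fps/1000)`, clamped at 0, consumes only the
frame rate (typically 25 fps) and the trim offset of an externally
trimmed recording. Default replay stepping is 100 ms of data time per
second of wall time.

## Gesture coding (tactile protocol analysis)

The taxonomy distinguishes actions within an object (trace, glance,
fix, brush, scan-within, tap, hover), across objects (scan, comb, skim,
slideTo, jumpTo), across-and-within (span) and off-display (park,
break). Durations classify as short (< 0.5 s), medium (0.5–2 s, both
boundaries inclusive) and long (> 2 s); the three classes partition the
positive durations, and each label admits only particular classes
(e.g. tap: s; fix: m, l; trace: s, m, l).

Manual coding proceeds in four stages — specification (object names,
3×3 grid locations `(1,1)`…`(3,3)`, levels 1–3 from whole shape down to
individual sides/corners), first-pass coding, detailed coding, and
quantification. First-pass lines begin exactly when the set of occupied
(object, location) pairs changes, including to the empty set when all
digits lift; a zero-length empty change at the trial's very last row
closes the protocol rather than opening a line. Detailed codes are
clipped to their parent first-pass line; continuations across a line
boundary carry the `//` ("gesture continues as above") mark. Levels are
assigned from the action's bounding-box diagonal relative to the
object's: < 25 % ⇒ level 3, < 75 % ⇒ level 2, else level 1
(configurable).

### Automatic classification

The automatic classifier goes beyond the manual method: the taxonomy's
definitions are qualitative, so each is made operational by explicit
thresholds (`RuleParams`, all configurable):

| parameter | default | meaning |
|---|---|---|
| `stationary_radius` | 8 px | max wander of a "stationary" touch |
| `tap_max` | 150 ms | max duration of a momentary point touch |
| `pause_speed` / `pause_min_ms` | 40 px/s / 120 ms | what counts as a pause |
| `hand_radius` | 300 px | concurrent touches this close = one hand cluster |
| `jump_max` / `hover_min` | 1,000 / 500 ms | off-surface gap windows |
| `offsurface_min` | 2,000 ms | gaps beyond this flag park/break candidates |
| `min_move` / `reversal_cos` | 3 px / −0.5 | jitter floor; a reversal is a turn > 120° |
| `perimeter_tol` | 18 px | max distance to the outline for a trace |

Rule order is a fixed, documented tie-break: for single-AOI strokes
tap/fix (stationary, split on duration) before brush (≥ 2 direction
reversals, ≥ 500 ms) before trace (perimeter-proximal — measured against
the object outline when known, else the cell rectangle — with no
backtrack) before glance before scan-within; for multi-AOI strokes
slideTo (distinct endpoints, no intermediate pause) before scan (ordered
row/column traversal, pauses allowed) before skim. Because "one movement
in any direction" (scan-within) would otherwise absorb every brief
within-object movement, a stroke that *transits* the object (net
displacement ≥ 60 % of the cell size without slowing below the pause
threshold) classifies as glance ahead of scan-within. Square corners
(90° turns) deliberately do not count as reversals, so a clean perimeter
trace is not mistaken for a brush.

Between strokes of one ID: same object, gap ≥ 500 ms, no translation ⇒
hover; different AOI, gap < 1,000 ms ⇒ jumpTo; gap ≥ 2 s ⇒ a park/break
*candidate* flagged indeterminate — off-surface positions are simply not
in the log, so park and break cannot be distinguished without video.
For the same reason hand identity defaults to `unknown` and finger
patterns (`R⟨N⟩(⟨M⟩)`) are import-only fields for video-coded sheets.
Span detection requires a stationary anchor stroke and a temporally
overlapping stroke starting within `hand_radius` of it and ending in a
different AOI. Comb is compositional (≥ 2 systematic scans over adjacent
rows/columns) and is not emitted by the single-stroke classifier.

One taxonomy friction is worth noting: the inter-stroke rule admits
jumpTo gaps up to 1,000 ms, while the taxonomy marks jumpTo short-only.
The rule is kept as stated; the admissibility property is asserted over
the scripted corpus, whose durations sit inside the admissible classes
by construction.

## Synthetic generator

The generator is the package's ground-truth instrument, not a fixture.
It emulates the study conditions: a 3×3 stimulus of named shapes
(three fully-capitalized matching pairs + three mixed-case distractors,
shapes at 60 % of their 300×300 px cells within a 900×900 px capture
area), 60 Hz sampling cadence, up to ten digit slots with
lowest-free-ID assignment, a four-corner calibration header, per-axis
Gaussian positional jitter (σ in px, seeded; σ = 2 px stands in for
finger-pad noise at a scale tied to the 8 px stationary radius — real
capacitive jitter magnitudes are not established, so this is an
engineering choice), optional ±ms timestamp jitter (off by default) and
sensor-overload injection (contacts force-closed, resumed after the
given gap at their scheduled positions with freshly assigned IDs).

Timestamps are integer milliseconds, as in the raw format. A consequence
is that at 60 Hz the per-interval cadence alternates 16/17 ms; cadence
exactness (median interval = 1000/rate) therefore holds at rates whose
period is a whole millisecond (e.g. 50 Hz → 20 ms), while at 60 Hz the
*mean* interval is 16.67 ms ≤ 17 ms. Constant-velocity recovery is
likewise verified per-sample at 50 Hz (exact to < 1 %) and in the mean
at 60 Hz.

The demo corpus (`build_demo_script`) sequences two repetitions of
trace, fix, tap, brush, slideTo, jumpTo (250 ms gap flanked by fixes),
hover (900 ms lift, return in place) and span across different objects,
with 1,500 ms inter-gesture gaps chosen to sit in the no-label window
(too long for a jump, too short for an off-surface candidate). Recovery
is scored truth-driven: a scripted interval counts as recovered when
some automatic code carries the same label and overlaps at least half of
it. On this corpus recovery is ≥ 90 % at σ ≤ 2 px and degrades
monotonically with σ (checked at σ = 0, 2, 8, 32).

### What the generator does not emulate

Real logs contain palm contacts, finger-pad merging/splitting, drift in
contact centroids, irregular per-device event batching, and — most
importantly — strategic behaviour (search order, rereading, bimanual
coordination). Passing tests therefore show that the pipeline's
*mechanics* (formats, expansion, measures, windows, rule geometry) are
correct and that the classifier recovers cleanly scripted gestures under
positional noise; they do not certify classifier accuracy on human data,
for which the manual coding pathway (and its video-derived hand/finger
fields) remains the reference.

## Numerical choices and degenerate inputs

- Half-open conventions everywhere a boundary must be owned: AOI cells
  `[x0, x1) × [y0, y1)` with the last column/row closed so the grid tiles
  the bounds exactly; replay windows `(t_end − trail, t_end]`; histogram
  bins `[k·w, (k+1)·w)`.
- Speed with Δt = 0 between a digit's consecutive positions is skipped
  with a warning (simultaneous events for one digit are malformed but
  tolerated).
- Empty logs/tables yield empty distributions rather than errors;
  strokes left open at log end are closed at the last sample and
  flagged; parsing has a strict mode (raise) and a lenient mode (skip
  malformed lines with a warning naming the line).
- Calibration fitting rejects corner sets with no spread on an axis;
  fitted scales are reported signed so an inverted axis is visible.

## Problem sizes

The test suite and acceptance script run on synthetic inputs sized for
desk-scale reproducibility: demo corpora of ~900 events (~40 s of data),
dense 20,000-event streams for exact frame-overlap intersection, and a
100×100 lattice for AOI brute-force agreement. All quantities they
report are computed at run time from these inputs.

## Known limitations

- Rectangular/grid AOIs only; no polygonal AOIs or image-based shape
  extraction.
- The transform family has no rotation/shear term (residuals flag the
  need, but correction is out of scope).
- park/break, hand identity and finger identity are fundamentally
  unobservable from the log; automatic codes mark them unknown or
  indeterminate rather than guessing.
- The classifier's glance/scan-within boundary is intentionally crude —
  these labels overlap in the taxonomy itself and are excluded from the
  recovery guarantee.
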