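"""Calibration fitting, device-to-stimulus mapping, and areas of interest.

The experimenter calibrates a trial by touching four marks at the far
corners of the tactile stimulus; from the four (device point, stimulus
corner) correspondences we fit an axis-aligned scale-plus-offset transform
(no rotation/shear — the stimulus paper is affixed square to the screen, so
only offsets and scaling are needed; residuals are reported so a rotated
sheet is detectable).

Areas of interest (AOIs) are half-open rectangular cells, typically a
uniform rows x cols grid over the touch-capture area, with grid locations
running (1, 1) top-left to (rows, cols) bottom-right.  The right/bottom
edges of the last column/row are closed so the cells tile the bounds
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Rect",
    "StimulusTransform",
    "AoiCell",
    "AoiMap",
    "fit_transform",
    "apply_transform",
    "make_grid_aois",
    "assign_aoi",
]

Point = tuple[float, float]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle, origin top-left, y downward."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        if self.x1 <= self.x0 or self.y1 <= self.y0:
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    def corners(self) -> list[Point]:
        """Top-left, top-right, bottom-left, bottom-right."""
        return [(self.x0, self.y0), (self.x1, self.y0), (self.x0, self.y1), (self.x1, self.y1)]

    def center(self) -> Point:
        return ((self.x0 + self.x1) / 2, (self.y0 + self.y1) / 2)


@dataclass(frozen=True)
class StimulusTransform:
    """Per-axis scale+offset mapping device pixels to stimulus coordinates.

    The forward map is ``p' = (p - offset) * scale`` per axis; it is
    invertible (scales are strictly positive in practice but only required
    non-zero).  ``residuals`` holds the per-corner fit residuals in target
    units, so a mis-affixed (rotated) stimulus is detectable.
    """

    scale_x: float
    scale_y: float
    offset_x: float
    offset_y: float
    residuals: tuple[float, ...] = ()
    source_resolution: tuple[int, int] | None = None
    target_resolution: tuple[int, int] | None = None

    def apply(self, p: Point) -> Point:
        return ((p[0] - self.offset_x) * self.scale_x, (p[1] - self.offset_y) * self.scale_y)

    def invert(self, p: Point) -> Point:
        return (p[0] / self.scale_x + self.offset_x, p[1] / self.scale_y + self.offset_y)

    @classmethod
    def identity(cls) -> "StimulusTransform":
        return cls(1.0, 1.0, 0.0, 0.0)


class CalibrationFitError(ValueError):
    """Degenerate calibration correspondences (collinear/duplicated corners)."""


def fit_transform(
    calibration: list[Point],
    reference: list[Point],
    source_resolution: tuple[int, int] | None = None,
    target_resolution: tuple[int, int] | None = None,
) -> StimulusTransform:
    """Least-squares per-axis scale+offset from four corner correspondences.

    Parameters
    ----------
    calibration:
        Device points registered by the experimenter (corner order must
        match ``reference``).
    reference:
        The stimulus corners the marks correspond to.

    The per-axis model ``target = a * device + b`` is solved in closed form
    (ordinary least squares); the returned transform uses ``scale = a`` and
    ``offset = -b / a`` so that ``apply(p) = (p - offset) * scale``.
    """
    if len(calibration) != len(reference) or len(calibration) < 2:
        raise CalibrationFitError("need matching device/reference corner lists (>= 2 points)")
    dev = np.asarray(calibration, dtype=float)
    ref = np.asarray(reference, dtype=float)
    scales, offsets, resid = [], [], None
    fitted = np.empty_like(ref)
    for axis in range(2):
        d, r = dev[:, axis], ref[:, axis]
        if np.ptp(d) == 0 or np.ptp(r) == 0:
            raise CalibrationFitError(
                f"degenerate corner set: no spread on axis {'xy'[axis]}"
            )
        a, b = np.polyfit(d, r, 1)
        if a == 0:
            raise CalibrationFitError("zero scale fitted")
        scales.append(float(a))
        offsets.append(float(-b / a))
        fitted[:, axis] = a * d + b
    resid = tuple(float(v) for v in np.linalg.norm(fitted - ref, axis=1))
    return StimulusTransform(
        scales[0], scales[1], offsets[0], offsets[1], resid, source_resolution, target_resolution
    )


def apply_transform(tf: StimulusTransform, p: Point) -> Point:
    """Map a device point into stimulus coordinates (see transform docs)."""
    return tf.apply(p)


@dataclass(frozen=True)
class AoiCell:
    """One named AOI cell with its 1-based grid location and object name."""

    name: str
    row: int
    col: int
    rect: Rect
    object_name: str = ""
    closed_right: bool = False
    closed_bottom: bool = False

    def contains(self, p: Point) -> bool:
        x, y = p
        in_x = self.rect.x0 <= x < self.rect.x1 or (self.closed_right and x == self.rect.x1)
        in_y = self.rect.y0 <= y < self.rect.y1 or (self.closed_bottom and y == self.rect.y1)
        return in_x and in_y

    @property
    def location(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass
class AoiMap:
    """Named areas of interest tiling the capture area.

    ``outlines`` optionally maps object names to outline polygons (lists of
    stimulus-coordinate points); gesture rules fall back to cell-rectangle
    geometry when absent.
    """

    bounds: Rect
    cells: list[AoiCell]
    rows: int = 0
    cols: int = 0
    outlines: dict[str, list[Point]] = field(default_factory=dict)

    def cell_at(self, row: int, col: int) -> AoiCell:
        for cell in self.cells:
            if cell.row == row and cell.col == col:
                return cell
        raise KeyError((row, col))

    def by_object(self, object_name: str) -> AoiCell:
        for cell in self.cells:
            if cell.object_name == object_name:
                return cell
        raise KeyError(object_name)


def make_grid_aois(
    bounds: Rect,
    rows: int,
    cols: int,
    object_names: list[str] | None = None,
) -> AoiMap:
    """Split ``bounds`` into a uniform rows x cols grid of half-open cells.

    The nine cells of the usual 3x3 split associate each touch with the
    shape occupying that cell.  Object names, if given, attach row-major.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if object_names is not None and len(object_names) != rows * cols:
        raise ValueError(f"expected {rows * cols} object names, got {len(object_names)}")
    xs = np.linspace(bounds.x0, bounds.x1, cols + 1)
    ys = np.linspace(bounds.y0, bounds.y1, rows + 1)
    cells = []
    for r in range(rows):
        for c in range(cols):
            idx = r * cols + c
            cells.append(
                AoiCell(
                    name=f"({r + 1},{c + 1})",
                    row=r + 1,
                    col=c + 1,
                    rect=Rect(xs[c], ys[r], xs[c + 1], ys[r + 1]),
                    object_name=object_names[idx] if object_names else "",
                    closed_right=(c == cols - 1),
                    closed_bottom=(r == rows - 1),
                )
            )
    return AoiMap(bounds=bounds, cells=cells, rows=rows, cols=cols)


def assign_aoi(aoi_map: AoiMap, p: Point) -> AoiCell | None:
    """Unique cell containing ``p`` under the half-open tiling, else None.

    Interior shared edges belong to the right/lower neighbour's left/upper
    edge, i.e. the cell for which the coordinate is an inclusive lower
    bound; points outside the bounds map to None.
    """
    for cell in aoi_map.cells:
        if cell.contains(p):
            return cell
    return None
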