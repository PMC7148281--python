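"""Stepped time-window replay frames and touch/video timeline mapping.

A replay frame shows the trail of touch events in the half-open window
``(t_end - trail, t_end]`` — the frame's labelled end time is inclusive.
Stepping the end time by less than the trail length leaves successive
frames sharing ``trail - step`` milliseconds of events (e.g. step 1,000 ms
with a 1,200 ms trail shares 200 ms), which aids reading the flow of
touches across frames.

Replay speed is governed by the stepping value in milliseconds of data
time per second of wall time (default 100 ms/s, i.e. 10% of real time).
The companion video is never decoded here; only its frame rate and trim
offset are used to interpolate a data timestamp to a video frame index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .geometry import StimulusTransform
from .log_io import TouchEvent

__all__ = [
    "DEFAULT_PLAY_STEPPING",
    "ReplaySettings",
    "Frame",
    "Dot",
    "frame_at",
    "frame_sequence",
    "render_frame",
    "data_time_advance",
    "video_frame_index",
]

DEFAULT_PLAY_STEPPING = 100  # ms of data time per second of replay

PALETTE_SIZE = 10  # one colour per input ID slot; colour encodes contact order


@dataclass(frozen=True)
class ReplaySettings:
    """Frame stepping/trail configuration."""

    step: int
    trail: int
    play_stepping: int = DEFAULT_PLAY_STEPPING

    def __post_init__(self):
        if self.step <= 0 or self.trail <= 0:
            raise ValueError("step and trail must be positive")

    @property
    def overlap(self) -> int:
        """Milliseconds of events shared by successive frames."""
        return max(self.trail - self.step, 0)


@dataclass(frozen=True)
class Frame:
    """Events in the half-open window (t_end - trail, t_end]."""

    t_end: int
    trail: int
    events: tuple[TouchEvent, ...]


@dataclass(frozen=True)
class Dot:
    """One plot-ready dot: stimulus coordinates plus a palette index."""

    x: float
    y: float
    color_index: int
    t: int
    input_id: int


def frame_at(events: list[TouchEvent], t_end: int, trail: int) -> Frame:
    """Exactly the events with ``t_end - trail < t <= t_end``."""
    if trail <= 0:
        raise ValueError("trail must be positive")
    lo = t_end - trail
    return Frame(t_end=t_end, trail=trail, events=tuple(e for e in events if lo < e.t <= t_end))


def frame_sequence(
    events: list[TouchEvent], t_start: int, t_stop: int, step: int, trail: int
) -> list[Frame]:
    """Frames ending at t_start+step, t_start+2*step, ... covering t_stop.

    When ``trail >= step`` the union of the frames covers every event in
    ``(t_start, t_stop]``; with ``trail < step`` events falling in the
    inter-frame gaps appear in no frame (a documented loss).
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if t_start > t_stop:
        raise ValueError("t_start must be <= t_stop")
    n = max(1, math.ceil((t_stop - t_start) / step)) if t_stop > t_start else 0
    return [frame_at(events, t_start + k * step, trail) for k in range(1, n + 1)]


def render_frame(
    frame: Frame,
    transform: StimulusTransform,
    annotate_timestamps: bool = False,
) -> list[Dot]:
    """Map a frame's events into stimulus coordinates as coloured dots.

    Each distinct input ID gets a fixed palette index (``id % 10``); two
    disjoint runs of the same colour are two separate touches, possibly by
    different fingers (colour encodes contact order, not finger identity).
    The rendering backend is pluggable: this returns geometry + colour
    indices only, so callers can draw with any plotting library.
    """
    if transform is None:
        raise ValueError("a device-to-stimulus transform is required to render")
    dots = []
    for ev in frame.events:
        x, y = transform.apply((ev.x, ev.y))
        dots.append(Dot(x=x, y=y, color_index=ev.input_id % PALETTE_SIZE, t=ev.t, input_id=ev.input_id))
    return dots


def data_time_advance(wall_seconds: float, play_stepping: int = DEFAULT_PLAY_STEPPING) -> float:
    """Milliseconds of data time advanced by ``wall_seconds`` of replay."""
    return wall_seconds * play_stepping


def video_frame_index(t: int, fps: float, offset: int = 0) -> int:
    """Interpolate a data timestamp to a video frame number.

    ``floor((t - offset) * fps / 1000)``, clamped at 0 (timestamps before
    the trimmed video start warn and map to frame 0); monotone
    non-decreasing in ``t``.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    if t < offset:
        warnings.warn(f"timestamp {t} precedes video offset {offset}; clamping to frame 0",
                      stacklevel=2)
        return 0
    return int(math.floor((t - offset) * fps / 1000.0))
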