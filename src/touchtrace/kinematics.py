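"""Derived kinematic and dwell measures over the digit-state table.

Speed of a touch movement is the Euclidean distance between a digit's
position in a record and its position in the immediately preceding record,
divided by the time between the two records (scaled to per-second).  A
"record" is one digit-state row, i.e. one distinct event timestamp.  The
first sample of each contact segment has no predecessor, so its speed is
undefined and omitted (not zero).

Row summaries give the mean and maximum of the per-digit speeds in a
record: with a single digit the two are equal; with one stationary digit
(speed 0) and one moving at v, the mean is v/2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AoiMap, assign_aoi
from .state_table import (
    EVENT_DOWN,
    EVENT_ERROR,
    EVENT_MOVE,
    EVENT_STAT,
    EVENT_UP,
    IN_USE,
    N_DIGITS,
    DigitStateRow,
)

__all__ = [
    "SpeedSample",
    "RowSpeedSummary",
    "touch_speeds",
    "row_summaries",
    "concurrency_distribution",
    "speed_histogram",
    "dwell_proportions",
    "sampling_capacity",
    "summaries_frame",
]


@dataclass(frozen=True)
class SpeedSample:
    """Instantaneous speed of one digit at one record, pixels/second."""

    t: int
    digit: int
    speed: float


@dataclass(frozen=True)
class RowSpeedSummary:
    """Mean/max speed and concurrency for one record."""

    t: int
    mean_speed: float
    max_speed: float
    n_digits_in_use: int


def touch_speeds(rows: list[DigitStateRow]) -> list[SpeedSample]:
    """Per-digit speeds between consecutive records of a contact segment.

    STAT-to-STAT pairs yield 0 (position carried forward).  A zero time
    difference between a digit's consecutive positions is skipped with a
    warning.  DOWN resets the segment, so the first sample after DOWN is
    the earliest with a defined speed; ERROR and UP close the segment.
    """
    samples: list[SpeedSample] = []
    prev: dict[int, tuple[int, tuple[float, float]]] = {}
    for row in rows:
        for d in range(N_DIGITS):
            e = row.events[d]
            if e is None:
                continue
            pos = row.positions[d]
            if e == EVENT_DOWN:
                prev[d] = (row.t, pos)
                continue
            if e == EVENT_ERROR:
                prev.pop(d, None)
                continue
            if e in (EVENT_MOVE, EVENT_STAT, EVENT_UP):
                if d in prev:
                    t0, p0 = prev[d]
                    dt = row.t - t0
                    if dt == 0:
                        warnings.warn(
                            f"digit {d}: zero time delta at t={row.t}, sample skipped",
                            stacklevel=2,
                        )
                    else:
                        dist = math.hypot(pos[0] - p0[0], pos[1] - p0[1])
                        samples.append(SpeedSample(row.t, d, dist / dt * 1000.0))
                if e == EVENT_UP:
                    prev.pop(d, None)
                else:
                    prev[d] = (row.t, pos)
    return samples


def row_summaries(rows: list[DigitStateRow]) -> list[RowSpeedSummary]:
    """Mean/max over defined per-digit speeds in each record.

    Records in which no digit has a defined speed are omitted.
    ``n_digits_in_use`` counts digits stationary or moving (DOWN, MOVE or
    STAT) in the record.
    """
    by_t: dict[int, list[float]] = {}
    for s in touch_speeds(rows):
        by_t.setdefault(s.t, []).append(s.speed)
    out = []
    for row in rows:
        speeds = by_t.get(row.t)
        if not speeds:
            continue
        out.append(
            RowSpeedSummary(
                t=row.t,
                mean_speed=float(np.mean(speeds)),
                max_speed=float(np.max(speeds)),
                n_digits_in_use=row.n_digits_in_use,
            )
        )
    return out


def _row_weights(rows: list[DigitStateRow], weighting: str) -> np.ndarray:
    if weighting == "records":
        return np.ones(len(rows))
    if weighting != "time":
        raise ValueError(f"unknown weighting {weighting!r}")
    # forward interval to the next row; the last row carries no weight
    ts = np.array([r.t for r in rows], dtype=float)
    w = np.diff(ts, append=ts[-1] if len(ts) else 0.0)
    return w


def concurrency_distribution(
    rows: list[DigitStateRow], weighting: str = "time"
) -> dict[int, float]:
    """Proportion of touched time with 1..10 digits in use.

    Time weighting uses the forward interval to the next record (the last
    record weighs 0); ``weighting="records"`` counts records instead.
    Proportions over the touched time sum to 1; records with no digit in
    use are excluded.
    """
    if not rows:
        return {}
    w = _row_weights(rows, weighting)
    totals: dict[int, float] = {}
    for row, weight in zip(rows, w):
        n = row.n_digits_in_use
        if n >= 1:
            totals[n] = totals.get(n, 0.0) + weight
    grand = sum(totals.values())
    if grand == 0:
        return {}
    return {n: v / grand for n, v in sorted(totals.items())}


def speed_histogram(
    summaries: list[RowSpeedSummary], bin_width: float, which: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of records per half-open speed bin [k*w, (k+1)*w).

    Returns ``(edges, counts)``; the total count equals the number of
    summarized records regardless of bin width.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if which not in ("mean", "max"):
        raise ValueError("which must be 'mean' or 'max'")
    vals = np.array(
        [s.mean_speed if which == "mean" else s.max_speed for s in summaries], dtype=float
    )
    if len(vals) == 0:
        return np.array([0.0, bin_width]), np.array([0])
    n_bins = int(np.floor(vals.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * float(bin_width)
    idx = np.floor(vals / bin_width).astype(int)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts


def dwell_proportions(
    rows: list[DigitStateRow],
    aois: AoiMap,
    rule: str = "any",
    weighting: str = "time",
) -> dict[str, float]:
    """Proportion of touched time spent in each area of interest.

    Under the default ``rule="any"`` a record's interval is credited to
    every AOI that any in-contact digit occupies, so proportions may sum to
    more than 1 when digits sit in different cells simultaneously.  Under
    ``rule="primary"`` only the lowest active input ID counts.  Positions
    outside the AOI bounds accrue under ``"none"``.  Proportions are of the
    total touched time (records with >= 1 digit in use).
    """
    if rule not in ("any", "primary"):
        raise ValueError("rule must be 'any' or 'primary'")
    if not rows:
        return {}
    w = _row_weights(rows, weighting)
    per_aoi: dict[str, float] = {}
    touched = 0.0
    for row, weight in zip(rows, w):
        digits = row.digits_in_use()
        if not digits:
            continue
        touched += weight
        if rule == "primary":
            digits = digits[:1]
        names = set()
        for d in digits:
            cell = assign_aoi(aois, row.positions[d])
            names.add(cell.name if cell is not None else "none")
        for name in names:
            per_aoi[name] = per_aoi.get(name, 0.0) + weight
    if touched == 0:
        return {}
    return {name: v / touched for name, v in sorted(per_aoi.items())}


def sampling_capacity(duration_s: float, rate_hz: float, n_digits: int = 1) -> int:
    """Theoretical maximum number of recorded touch states.

    A 5-minute trial at the ~60 Hz screen refresh rate can generate just
    under 18,000 states per digit (180,000 for ten digits in simultaneous
    use); actual logs run at about half that because of pauses and uneven
    digit use.
    """
    if duration_s < 0 or rate_hz <= 0 or n_digits < 0:
        raise ValueError("duration, rate and digit count must be positive")
    return int(math.floor(duration_s * rate_hz * n_digits))


def summaries_frame(summaries: list[RowSpeedSummary]) -> pd.DataFrame:
    """Tabular view of row summaries (for TSV export / spreadsheet use)."""
    return pd.DataFrame(
        {
            "t": [s.t for s in summaries],
            "mean_speed": [s.mean_speed for s in summaries],
            "max_speed": [s.max_speed for s in summaries],
            "n_digits_in_use": [s.n_digits_in_use for s in summaries],
        }
    )
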