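"""Per-spot movement measures for telomere-led chromosome movements.

Four quantities summarize the motion of a fluorescently tagged chromosomal
locus tracked in 2D projection at uniform (1 s) intervals:

* **maximum speed** — the single longest step, in projected µm/s;
* **average speed** — the mean step length, in projected µm/s;
* **bias** — the mean cosine of the turning angles between successive
  displacement vectors (0 for a memoryless random walk, negative for a
  tendency to remain in place, positive for directed travel);
* **area** — the area of the axis-aligned bounding box enclosing all spot
  positions within a time window, in µm², averaged over the complete
  non-overlapping windows tiling the track.

Population summaries use the median as the center and the average absolute
deviation from the median (AAD) as dispersion, because per-spot measures are
strongly non-normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SpotTrack",
    "MovementSummary",
    "step_vectors",
    "max_speed",
    "avg_speed",
    "bias",
    "bbox_area",
    "summarize_track",
    "summarize_population",
]


@dataclass
class SpotTrack:
    """A single tracked spot: 2D projected positions at uniform intervals.

    Parameters
    ----------
    positions : (n, 2) array
        Projected (x, y) coordinates in µm, one row per frame.
    dt_s : float
        Acquisition interval in seconds (default 1).
    timepoint_h : float or None
        Hours after induction of meiosis (the t# of the sporulation
        time course).
    paired : bool or None
        Whether the nucleus showed one spot (paired homologs) or two.
    """

    positions: np.ndarray
    dt_s: float = 1.0
    cell_id: str = ""
    spot_id: str = ""
    timepoint_h: float | None = None
    paired: bool | None = None
    genotype: str = ""
    locus: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array of x, y in µm")
        if self.positions.shape[0] < 2:
            raise ValueError("a track needs at least 2 positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if not (np.isfinite(self.dt_s) and self.dt_s > 0):
            raise ValueError("dt_s must be a positive finite number")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.dt_s


@dataclass
class MovementSummary:
    """The four movement measures for one spot."""

    max_speed: float
    avg_speed: float
    bias: float
    area: float
    window_s: float
    n_steps: int
    n_angles: int

    def __post_init__(self) -> None:
        if self.max_speed < self.avg_speed - 1e-12:
            raise ValueError("max_speed cannot be below avg_speed")
        if not np.isnan(self.bias) and not -1.0 - 1e-9 <= self.bias <= 1.0 + 1e-9:
            raise ValueError("bias must lie in [-1, 1]")


def step_vectors(track: SpotTrack) -> np.ndarray:
    """Displacement vectors between successive frames, shape (n-1, 2), µm."""
    return np.diff(track.positions, axis=0)


def _step_lengths(track: SpotTrack) -> np.ndarray:
    return np.linalg.norm(step_vectors(track), axis=1)


def max_speed(track: SpotTrack) -> float:
    """Longest single step divided by the frame interval (projected µm/s)."""
    return float(_step_lengths(track).max() / track.dt_s)


def avg_speed(track: SpotTrack) -> float:
    """Mean step length divided by the frame interval (projected µm/s)."""
    return float(_step_lengths(track).mean() / track.dt_s)


def bias(track: SpotTrack, return_n_angles: bool = False):
    """Mean cosine of turning angles between successive displacement vectors.

    Zero-length steps have no direction and are dropped before forming
    angles; the cosine is then taken between each remaining vector and the
    next.  Returns NaN if fewer than two non-degenerate steps remain (the
    angle count is 0 in that case).
    """
    vec = step_vectors(track)
    lengths = np.linalg.norm(vec, axis=1)
    vec = vec[lengths > 0]
    lengths = lengths[lengths > 0]
    if vec.shape[0] < 2:
        result, n_angles = float("nan"), 0
    else:
        unit = vec / lengths[:, None]
        cosines = np.einsum("ij,ij->i", unit[:-1], unit[1:])
        np.clip(cosines, -1.0, 1.0, out=cosines)
        result, n_angles = float(cosines.mean()), cosines.size
    if return_n_angles:
        return result, n_angles
    return result


def bbox_area(
    track: SpotTrack,
    window_s: float | None = None,
    *,
    mode: str = "mean",
    rotated: bool = False,
) -> float:
    """Bounding-box area per time window, µm².

    The track is tiled into consecutive windows of ``window_s`` seconds
    (``window_s/dt + 1`` positions; adjacent windows share their boundary
    frame).  Per window the area of the box enclosing all positions is
    taken; the per-spot value is the mean over complete windows
    (``mode="mean"``) or the first window only (``mode="first"``).

    By default the box is axis-aligned.  ``rotated=True`` instead uses the
    minimum-area enclosing rectangle over all orientations (rotating
    calipers on the convex hull).

    ``window_s=None`` uses the whole track as a single window.
    """
    if window_s is None:
        window_s = track.duration_s
    n_win = int(round(window_s / track.dt_s))  # steps per window
    if n_win < 1 or n_win > track.n_frames - 1:
        raise ValueError(
            f"window of {window_s} s does not fit a track of "
            f"{track.duration_s} s duration"
        )
    pos = track.positions
    areas = []
    for start in range(0, track.n_frames - n_win, n_win):
        win = pos[start : start + n_win + 1]
        areas.append(_rect_area(win) if rotated else _aabb_area(win))
    if mode == "first":
        return float(areas[0])
    if mode == "mean":
        return float(np.mean(areas))
    raise ValueError(f"unknown mode {mode!r}")


def _aabb_area(points: np.ndarray) -> float:
    mins = points.min(axis=0)
    maxs = points.max(axis=0)
    return float((maxs[0] - mins[0]) * (maxs[1] - mins[1]))


def _rect_area(points: np.ndarray) -> float:
    """Minimum-area enclosing rectangle over all orientations."""
    from scipy.spatial import QhullError, ConvexHull

    uniq = np.unique(points, axis=0)
    if uniq.shape[0] < 3:
        return 0.0
    try:
        hull = uniq[ConvexHull(uniq).vertices]
    except QhullError:  # collinear points
        return 0.0
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles = np.arctan2(edges[:, 1], edges[:, 0])
    best = np.inf
    for a in angles:
        c, s = np.cos(-a), np.sin(-a)
        rot = hull @ np.array([[c, -s], [s, c]]).T
        best = min(best, _aabb_area(rot))
    return float(best)


def summarize_track(track: SpotTrack, window_s: float | None = 60.0) -> MovementSummary:
    """All four measures for one track at the given area window."""
    if window_s is not None and window_s > track.duration_s:
        window_s = track.duration_s
    b, n_angles = bias(track, return_n_angles=True)
    return MovementSummary(
        max_speed=max_speed(track),
        avg_speed=avg_speed(track),
        bias=b,
        area=bbox_area(track, window_s),
        window_s=window_s if window_s is not None else track.duration_s,
        n_steps=track.n_frames - 1,
        n_angles=n_angles,
    )


MEASURES = ("max_speed", "avg_speed", "bias", "area")


def tracks_to_table(
    tracks: Iterable[SpotTrack], window_s: float | None = 60.0
) -> pd.DataFrame:
    """Long-format per-spot table of the four measures plus metadata."""
    rows = []
    for t in tracks:
        s = summarize_track(t, window_s)
        rows.append(
            dict(
                cell_id=t.cell_id,
                spot_id=t.spot_id,
                genotype=t.genotype,
                locus=t.locus,
                timepoint_h=t.timepoint_h,
                paired=t.paired,
                max_speed=s.max_speed,
                avg_speed=s.avg_speed,
                bias=s.bias,
                area=s.area,
                window_s=s.window_s,
                n_steps=s.n_steps,
                n_angles=s.n_angles,
            )
        )
    return pd.DataFrame(rows)


def aad(values: Sequence[float]) -> float:
    """Average absolute deviation from the median."""
    v = np.asarray(values, dtype=float)
    return float(np.mean(np.abs(v - np.median(v))))


def summarize_population(
    tracks: Iterable[SpotTrack] | pd.DataFrame,
    stratify_by: Sequence[str] = ("genotype", "paired"),
    window_s: float | None = 60.0,
) -> pd.DataFrame:
    """Per-stratum medians and dispersions of the four movement measures.

    ``stratify_by`` names metadata columns (``genotype``, ``paired``,
    ``timepoint_h``, ``locus``).  Each stratum row carries, per measure, the
    median, the average absolute deviation from the median, and n.  Strata
    that are empty after dropping NaN measures are omitted.
    """
    table = (
        tracks
        if isinstance(tracks, pd.DataFrame)
        else tracks_to_table(tracks, window_s)
    )
    if table.empty:
        raise ValueError("no tracks to summarize")
    stratify_by = list(stratify_by)
    rows = []
    for key, grp in table.groupby(stratify_by, dropna=False):
        if not isinstance(key, tuple):
            key = (key,)
        row = dict(zip(stratify_by, key))
        row["n"] = len(grp)
        for m in MEASURES:
            vals = grp[m].dropna().to_numpy()
            row[f"{m}_median"] = float(np.median(vals)) if vals.size else float("nan")
            row[f"{m}_aad"] = aad(vals) if vals.size else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
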