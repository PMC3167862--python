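"""Run/rest segmentation of arc-length series and population statistics.

A *rest* is a maximal stretch of more than 14 frames (0.5 s at 28
frames/s) during which the particle's contour position x(T) stays within
one pixel (85 nm).  The sections between rests count as *runs* when
their total displacement is at least 85 nm and proceeds at a mean rate
of at least 0.17 µm/s; sections failing the run test are merged into the
adjacent rests.  Population summaries report the percentage of tracked
time spent running (mean ± s.e.m. across movies) and the percentage of
particles that never ran.  Direction is classified against the vector
from the track start to the cell centre: a track is *outward* when its
net-displacement vector makes an angle of less than 90° with the
outward radial direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import AcquisitionGeometry
from .track_ops import Track

__all__ = [
    "Interval",
    "MotionAnnotation",
    "PopulationSummary",
    "DirectionResult",
    "classify_runs_rests",
    "summarize_population",
    "classify_direction",
    "select_long_tracks",
    "REST_DISPLACEMENT",
    "REST_FRAMES",
    "MIN_RUN_RATE",
]

REST_DISPLACEMENT = 0.085  # µm: one pixel at 11.72 px/µm
REST_FRAMES = 14  # rests must span MORE than this many frames (0.5 s at 28 fps)
MIN_RUN_RATE = 0.17  # µm/s: 85 nm per 0.5 s


@dataclass
class Interval:
    label: str  # "run" | "rest"
    start: int  # frame index (inclusive)
    end: int  # frame index (inclusive)
    displacement: float  # signed x displacement over the interval, µm
    rate: float  # |displacement| / duration, µm/s


@dataclass
class MotionAnnotation:
    """Partition of one track into runs and rests.

    Intervals are contiguous, non-overlapping and cover every frame of
    the track exactly once.
    """

    track_id: int
    intervals: list[Interval]
    n_frames: int
    movie_id: int = 0

    def frame_labels(self) -> np.ndarray:
        labels = np.empty(self.n_frames, dtype="<U4")
        for iv in self.intervals:
            labels[iv.start : iv.end + 1] = iv.label
        return labels

    @property
    def run_frame_count(self) -> int:
        return int(sum(iv.end - iv.start + 1 for iv in self.intervals if iv.label == "run"))

    @property
    def run_time_fraction(self) -> float:
        return self.run_frame_count / self.n_frames

    @property
    def ever_ran(self) -> bool:
        return any(iv.label == "run" for iv in self.intervals)


@dataclass
class PopulationSummary:
    pct_time_running: float
    pct_time_running_sem: float
    pct_never_running: float
    n_tracks: int
    n_movies: int
    n_raw_tracks: int | None = None
    n_stitched_tracks: int | None = None


def _rest_mask(x: np.ndarray, rest_disp: float, rest_frames: int) -> np.ndarray:
    """Frames covered by any window of > rest_frames frames with x-range < rest_disp.

    Two-pointer sweep with monotonic deques: for each start i the largest
    j with max(x[i..j]) - min(x[i..j]) < rest_disp is found in O(n).
    """
    n = len(x)
    mask = np.zeros(n, dtype=bool)
    from collections import deque

    maxq: deque[int] = deque()
    minq: deque[int] = deque()
    j = -1
    for i in range(n):
        if j < i:
            j = i - 1
        while j + 1 < n:
            v = x[j + 1]
            # would adding j+1 keep the range below the threshold?
            new_max = max(x[maxq[0]], v) if maxq else v
            new_min = min(x[minq[0]], v) if minq else v
            if new_max - new_min >= rest_disp:
                break
            j += 1
            while maxq and x[maxq[-1]] <= v:
                maxq.pop()
            maxq.append(j)
            while minq and x[minq[-1]] >= v:
                minq.pop()
            minq.append(j)
        if j - i > rest_frames:
            mask[i : j + 1] = True
        # slide window start
        if maxq and maxq[0] == i:
            maxq.popleft()
        if minq and minq[0] == i:
            minq.popleft()
    return mask


def classify_runs_rests(
    x_series: np.ndarray,
    geom: AcquisitionGeometry,
    rest_disp: float = REST_DISPLACEMENT,
    rest_frames: int = REST_FRAMES,
    min_run_rate: float = MIN_RUN_RATE,
    track_id: int = 0,
    movie_id: int = 0,
) -> MotionAnnotation:
    """Partition an arc-length series x(T) into runs and rests.

    Frames belonging to any maximal window longer than ``rest_frames``
    frames with x-range below ``rest_disp`` are rests.  Each remaining
    section is a run iff its total |x| displacement is at least
    ``rest_disp`` and its mean rate at least ``min_run_rate``; failing
    sections are absorbed into the neighbouring rest.
    """
    x = np.asarray(x_series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("x_series must have at least 2 frames")
    dt = geom.frame_interval

    is_rest = _rest_mask(x, rest_disp, rest_frames)

    # provisional maximal sections
    sections: list[tuple[str, int, int]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or is_rest[i] != is_rest[start]:
            sections.append(("rest" if is_rest[start] else "cand", start, i - 1))
            start = i

    # decide candidate sections; failed candidates merge into rests
    labelled: list[tuple[str, int, int]] = []
    for label, a, b in sections:
        if label == "rest":
            labelled.append(("rest", a, b))
            continue
        disp = abs(x[b] - x[a])
        duration = max((b - a) * dt, dt)
        rate = disp / duration
        if disp >= rest_disp and rate >= min_run_rate:
            labelled.append(("run", a, b))
        else:
            labelled.append(("rest", a, b))

    # merge adjacent rests
    merged: list[tuple[str, int, int]] = []
    for label, a, b in labelled:
        if merged and merged[-1][0] == "rest" and label == "rest":
            merged[-1] = ("rest", merged[-1][1], b)
        else:
            merged.append((label, a, b))

    intervals = []
    for label, a, b in merged:
        disp = float(x[b] - x[a])
        duration = max((b - a) * dt, dt)
        intervals.append(Interval(label, a, b, disp, abs(disp) / duration))
    return MotionAnnotation(track_id=track_id, intervals=intervals, n_frames=n, movie_id=movie_id)


def summarize_population(
    annotations: list[MotionAnnotation],
    n_raw_tracks: int | None = None,
    n_stitched_tracks: int | None = None,
) -> PopulationSummary:
    """Population motility statistics over annotated tracks.

    The percentage of tracked time spent running is computed per movie
    (grouping by ``MotionAnnotation.movie_id``) and averaged with its
    standard error across movies; the never-running percentage is
    computed over particles.
    """
    if not annotations:
        raise ValueError("summarize_population requires at least one annotation")
    movies: dict[int, list[MotionAnnotation]] = {}
    for ann in annotations:
        movies.setdefault(ann.movie_id, []).append(ann)
    fractions = []
    for anns in movies.values():
        run = sum(a.run_frame_count for a in anns)
        tot = sum(a.n_frames for a in anns)
        fractions.append(run / tot)
    fractions = np.array(fractions)
    mean_pct = 100.0 * float(fractions.mean())
    sem_pct = (
        100.0 * float(fractions.std(ddof=1) / math.sqrt(len(fractions)))
        if len(fractions) > 1
        else 0.0
    )
    never = 100.0 * float(np.mean([not a.ever_ran for a in annotations]))
    return PopulationSummary(
        pct_time_running=mean_pct,
        pct_time_running_sem=sem_pct,
        pct_never_running=never,
        n_tracks=len(annotations),
        n_movies=len(movies),
        n_raw_tracks=n_raw_tracks,
        n_stitched_tracks=n_stitched_tracks,
    )


@dataclass
class DirectionResult:
    label: str  # "inward" | "outward" | "undefined"
    angle_deg: float  # angle between track vector and the outward radial direction


def classify_direction(track: Track, cell_centre) -> DirectionResult:
    """Classify a track as inward or outward relative to the cell centre.

    The angle is measured between the track's net-displacement vector and
    the outward radial direction (cell centre -> track start); the track
    is *outward* when this angle is strictly below 90°, which is the same
    classification as measuring against the start-to-centre vector and
    calling angles < 90° inward.  Exactly 90° classifies as inward.
    """
    centre = np.asarray(cell_centre, dtype=float)
    v = track.end - track.start
    nv = np.linalg.norm(v)
    if nv == 0:
        return DirectionResult("undefined", float("nan"))
    outward_radial = track.start - centre
    nr = np.linalg.norm(outward_radial)
    if nr == 0:
        # started exactly at the centre: any movement is outward
        return DirectionResult("outward", 0.0)
    cosang = float(np.clip(np.dot(v, outward_radial) / (nv * nr), -1.0, 1.0))
    angle = math.degrees(math.acos(cosang))
    return DirectionResult("outward" if angle < 90.0 else "inward", angle)


def select_long_tracks(
    tracks: list[Track],
    min_net_displacement: float = 2.0,
    direction: str | None = None,
    cell_centre=None,
) -> list[Track]:
    """Tracks whose start-to-end displacement exceeds the threshold.

    With ``direction`` set to "inward" or "outward" the subset is further
    filtered by :func:`classify_direction` (``cell_centre`` required).
    """
    selected = [t for t in tracks if t.net_displacement > min_net_displacement]
    if direction is not None:
        if cell_centre is None:
            raise ValueError("cell_centre is required for a direction filter")
        selected = [
            t for t in selected if classify_direction(t, cell_centre).label == direction
        ]
    return selected
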