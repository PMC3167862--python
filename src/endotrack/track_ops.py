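"""Track containers, stitching of broken tracks, and contour projection.

A :class:`Track` stores per-frame subpixel positions of one particle in
micrometres.  Tracking software drops particles that momentarily defocus,
so fragments whose end and start lie within 5 pixels and 14 frames of each
other are stitched back into one track (:func:`stitch`).  For run/rest
analysis each track is reduced to a spatially smoothed, coarsened contour
(:func:`build_contour`) and the particle's progress along that contour,
the arc-length series x(T) (:func:`project_track`).  Smoothing over a
length scale ``Lpix`` (~340 nm, four pixels) suppresses localization
noise while preserving genuine short-range movement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

DEFAULT_LPIX = 0.340  # µm; contour smoothing / coarsening length scale

__all__ = [
    "Track",
    "SmoothedContour",
    "stitch",
    "build_contour",
    "project_track",
    "DEFAULT_LPIX",
]


@dataclass
class Track:
    """Ordered per-frame positions of one particle, in micrometres.

    Attributes
    ----------
    track_id : int
    frames : ndarray of int
        Strictly increasing frame indices.
    positions : ndarray, shape (n, 2)
        (x, y) positions in µm.
    source : str
        ``"raw"`` for tracker output, ``"stitched"`` after merging.
    interpolated : frozenset of int
        Frames whose positions were filled by interpolation during
        stitching rather than observed.
    intensity : ndarray or None
        Optional per-frame spot intensity.
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray
    source: str = "raw"
    interpolated: frozenset = field(default_factory=frozenset)
    intensity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n, 2)")
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions must have equal length")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ValueError(f"track {self.track_id}: frames not strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"track {self.track_id}: non-finite positions")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start(self) -> np.ndarray:
        return self.positions[0]

    @property
    def end(self) -> np.ndarray:
        return self.positions[-1]

    @property
    def net_displacement(self) -> float:
        """Start-to-end Euclidean displacement in µm."""
        return float(np.linalg.norm(self.end - self.start))


@dataclass
class SmoothedContour:
    """Smoothed/coarsened polyline for one track plus its arc metric.

    ``smoothed_points`` has one point per track frame; ``coarse_vertices``
    is the coarsened polyline (spacing ~ Lpix, ends extrapolated) that
    defines the arc-length coordinate.  ``arc_positions`` is x(T) in µm
    with x = 0 at the track's first frame.
    """

    track_id: int
    smoothed_points: np.ndarray
    coarse_vertices: np.ndarray
    arc_positions: np.ndarray | None = None
    lpix: float = DEFAULT_LPIX
    degenerate: bool = False

    @property
    def length(self) -> float:
        """Total length of the coarse polyline in µm."""
        if len(self.coarse_vertices) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.coarse_vertices, axis=0), axis=1)))


# ---------------------------------------------------------------------------
# stitching


def _gap_admissible(a: Track, b: Track, max_gap_um: float, max_gap_frames: int):
    """Return (frame_gap, spatial_gap) if b can follow a, else None."""
    frame_gap = int(b.frames[0] - a.frames[-1])
    if frame_gap < 1 or frame_gap > max_gap_frames:
        return None
    spatial_gap = float(np.linalg.norm(b.positions[0] - a.positions[-1]))
    if spatial_gap > max_gap_um:
        return None
    return frame_gap, spatial_gap


def stitch(
    tracks: list[Track],
    max_gap_px: float = 5.0,
    max_gap_frames: int = 14,
    pixel_scale: float = 11.72,
) -> list[Track]:
    """Merge track fragments that belong to one particle.

    Two fragments are joined when one begins within ``max_gap_px`` pixels
    and at most ``max_gap_frames`` frames of the other's end.  Competing
    candidates are resolved by smallest frame gap, then smallest spatial
    gap.  Gap frames are filled by linear interpolation and flagged in
    ``Track.interpolated``; joins chain transitively, and the operation is
    idempotent.
    """
    max_gap_um = max_gap_px / pixel_scale
    tracks = sorted(tracks, key=lambda t: (t.frames[0], t.track_id))
    candidates = []
    for i, a in enumerate(tracks):
        for j, b in enumerate(tracks):
            if i == j:
                continue
            gap = _gap_admissible(a, b, max_gap_um, max_gap_frames)
            if gap is not None:
                candidates.append((gap[0], gap[1], i, j))
    candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3]))

    successor: dict[int, int] = {}
    tail_used: set[int] = set()
    head_used: set[int] = set()
    for _, _, i, j in candidates:
        if i in tail_used or j in head_used:
            continue
        successor[i] = j
        tail_used.add(i)
        head_used.add(j)

    out: list[Track] = []
    consumed: set[int] = set()
    for i in range(len(tracks)):
        if i in head_used or i in consumed:
            continue
        chain = [i]
        while chain[-1] in successor:
            chain.append(successor[chain[-1]])
        consumed.update(chain)
        if len(chain) == 1:
            out.append(tracks[i])
            continue
        out.append(_merge_chain([tracks[k] for k in chain]))
    return sorted(out, key=lambda t: t.track_id)


def _merge_chain(parts: list[Track]) -> Track:
    frames: list[int] = []
    positions: list[np.ndarray] = []
    interp: set[int] = set()
    for part in parts:
        if frames:
            f0, p0 = frames[-1], positions[-1]
            f1, p1 = int(part.frames[0]), part.positions[0]
            for f in range(f0 + 1, f1):
                w = (f - f0) / (f1 - f0)
                frames.append(f)
                positions.append((1 - w) * p0 + w * p1)
                interp.add(f)
        frames.extend(int(f) for f in part.frames)
        positions.extend(part.positions)
        interp.update(part.interpolated)
    return Track(
        track_id=parts[0].track_id,
        frames=np.array(frames),
        positions=np.array(positions),
        source="stitched",
        interpolated=frozenset(interp),
    )


# ---------------------------------------------------------------------------
# contour building


def build_contour(track: Track, lpix: float = DEFAULT_LPIX, project: bool = True) -> SmoothedContour:
    """Build the smoothed, coarsened contour of a track.

    The smoothing step replaces each point by the mean of all track points
    within ``lpix`` of it.  The coarse polyline is then built by walking
    the smoothed track from its first point, grouping consecutive points
    until the cumulative path separation exceeds ``lpix``, and emitting
    each group's mean; the terminal edges are extended linearly by
    ``lpix`` beyond the raw track's extremes so that projection never runs
    off the end of the polyline.
    """
    if len(track) < 2:
        raise ValueError("contour requires a track with at least 2 points")
    pts = track.positions
    dist = cdist(pts, pts)
    mask = (dist <= lpix).astype(float)
    smoothed = (mask @ pts) / mask.sum(axis=1)[:, None]

    step = np.linalg.norm(np.diff(smoothed, axis=0), axis=1)
    if np.allclose(step, 0.0):
        contour = SmoothedContour(
            track_id=track.track_id,
            smoothed_points=smoothed,
            coarse_vertices=smoothed[:1].copy(),
            lpix=lpix,
            degenerate=True,
        )
        contour.arc_positions = np.zeros(len(track))
        return contour

    vertices: list[np.ndarray] = []
    group_start = 0
    acc = 0.0
    for k in range(1, len(smoothed)):
        acc += step[k - 1]
        if acc > lpix:
            vertices.append(smoothed[group_start:k].mean(axis=0))
            group_start = k
            acc = 0.0
    vertices.append(smoothed[group_start:].mean(axis=0))
    coarse = np.array(vertices)

    if len(coarse) < 2:
        # Short track: fall back to the smoothed end points as the polyline.
        coarse = np.vstack([smoothed[0], smoothed[-1]])
        if np.allclose(coarse[0], coarse[1]):
            contour = SmoothedContour(
                track_id=track.track_id,
                smoothed_points=smoothed,
                coarse_vertices=coarse[:1],
                lpix=lpix,
                degenerate=True,
            )
            contour.arc_positions = np.zeros(len(track))
            return contour

    coarse = _extrapolate_ends(coarse, lpix)
    contour = SmoothedContour(
        track_id=track.track_id,
        smoothed_points=smoothed,
        coarse_vertices=coarse,
        lpix=lpix,
    )
    if project:
        contour.arc_positions = project_track(track, contour)
    return contour


def _extrapolate_ends(coarse: np.ndarray, lpix: float) -> np.ndarray:
    first_dir = coarse[0] - coarse[1]
    last_dir = coarse[-1] - coarse[-2]
    n0 = np.linalg.norm(first_dir)
    n1 = np.linalg.norm(last_dir)
    pre = coarse[0] + first_dir / n0 * lpix if n0 > 0 else coarse[0]
    post = coarse[-1] + last_dir / n1 * lpix if n1 > 0 else coarse[-1]
    return np.vstack([pre, coarse, post])


# ---------------------------------------------------------------------------
# projection


def project_track(track: Track, contour: SmoothedContour) -> np.ndarray:
    """Arc-length position series x(T) of a track along its contour.

    Each smoothed track point is projected onto the coarse polyline; x is
    the arc length to that projection, shifted so that the first frame
    maps to 0.  Self-approaching contours make the bare nearest-point
    rule ambiguous (two limbs can be spatially close but far apart in
    arc), so after the first frame the projection is restricted to an
    arc window of (raw inter-frame displacement + 2 Lpix) around the
    previously assigned arc position and the nearest point within that
    window is taken.  Near-ties therefore resolve toward the previous
    arc position, x is contraction-safe (|x(T+1) - x(T)| never exceeds
    the window), and tight contour bends are traversed continuously.
    If the windowed projection lands more than Lpix/2 farther from the
    point than the unrestricted nearest point, lock on the local limb is
    considered lost and the projection re-acquires the globally nearest
    one.
    """
    if contour.degenerate or len(contour.coarse_vertices) < 2:
        return np.zeros(len(track))
    verts = contour.coarse_vertices
    seg_vec = np.diff(verts, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    keep = seg_len > 0
    seg_vec, seg_len, seg_start = seg_vec[keep], seg_len[keep], verts[:-1][keep]
    if len(seg_len) == 0:
        return np.zeros(len(track))
    arc0 = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]

    pts = contour.smoothed_points
    raw_step = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
    eps = 0.020  # µm; limbs closer than this in distance count as tied

    def pick(d, arcs, prev):
        near = np.flatnonzero(d <= d.min() + eps)
        if prev is None:
            return near[np.argmin(arcs[near])]
        order = np.lexsort((arcs[near], np.abs(arcs[near] - prev)))
        return near[order[0]]

    x = np.empty(len(pts))
    prev_arc = None
    for i, p in enumerate(pts):
        rel = p - seg_start
        t_free = np.clip((rel * seg_vec).sum(axis=1) / seg_len**2, 0.0, 1.0)
        foot_free = seg_start + t_free[:, None] * seg_vec
        d_free = np.linalg.norm(foot_free - p[None, :], axis=1)
        arcs_free = arc0 + t_free * seg_len
        if prev_arc is None:
            x[i] = arcs_free[pick(d_free, arcs_free, None)]
            prev_arc = x[i]
            continue
        window = raw_step[i - 1] + 2 * contour.lpix
        lo, hi = prev_arc - window, prev_arc + window
        # clamp each edge's foot into the admissible arc interval
        t_lo = np.clip((lo - arc0) / seg_len, 0.0, 1.0)
        t_hi = np.clip((hi - arc0) / seg_len, 0.0, 1.0)
        t = np.clip(t_free, t_lo, t_hi)
        mask = (arc0 <= hi) & (arc0 + seg_len >= lo)
        if mask.any():
            foot = seg_start + t[:, None] * seg_vec
            d = np.linalg.norm(foot - p[None, :], axis=1)
            d[~mask] = np.inf
            arcs = arc0 + t * seg_len
            best = pick(d, arcs, prev_arc)
            if d[best] <= d_free.min() + contour.lpix / 2.0:
                x[i] = arcs[best]
                prev_arc = x[i]
                continue
        # lock lost (or window off the polyline): re-acquire globally
        x[i] = arcs_free[pick(d_free, arcs_free, prev_arc)]
        prev_arc = x[i]
    return x - x[0]
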