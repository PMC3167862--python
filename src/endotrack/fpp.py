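"""First-passage-probability (FPP) analysis of track populations.

For a passage length L, the first-passage time at starting time point T
of a track is the smallest non-negative lag t at which the Euclidean
displacement from the position at T first reaches L.  Passages are
collected from every time point of every track; replacing t with
u = L/t expresses the distribution as a speed.  Counts are normalized by
the total number of time points observed, so per-L probabilities are
comparable across conditions with different amounts of data.  Fixed-cell
(noise-only) tracks processed the same way estimate the static error:
the fraction of passages attributable to localization noise alone, which
is appreciable only for the shortest passage lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry
from .track_ops import Track

__all__ = [
    "FPPResult",
    "first_passage_times",
    "first_passage_times_bruteforce",
    "fpp_distribution",
    "mean_passage_speed",
    "static_error",
    "DEFAULT_L_SET",
    "default_speed_bins",
]

DEFAULT_L_SET = (0.1, 0.5, 1.0, 3.0, 5.0, 7.0, 9.0)  # µm

# tolerance for "displacement reaches L": guards the exact-boundary case
# (e.g. 14 steps of 2/28 µm) against float rounding
_EPS = 1e-9


def default_speed_bins(n_bins: int = 60, lo: float = 0.05, hi: float = 20.0) -> np.ndarray:
    """Logarithmic speed-bin edges in µm/s."""
    return np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)


@dataclass
class FPPResult:
    """Pooled first-passage record for one passage length L."""

    L: float
    start_frames: np.ndarray  # T of each recorded passage
    times: np.ndarray  # first-passage times t in seconds
    speeds: np.ndarray  # u = L / t in µm/s
    total_time_points: int
    bin_edges: np.ndarray | None = None
    bin_probability: np.ndarray | None = None

    @property
    def n_passages(self) -> int:
        return len(self.times)

    @property
    def total_probability(self) -> float:
        return self.n_passages / self.total_time_points if self.total_time_points else 0.0

    @property
    def passage_fraction(self) -> float:
        """Alias for total_probability: passages per observed time point."""
        return self.total_probability


def _first_passages_multi(
    track: Track, L_set, frame_interval: float, chunk: int = 1024
) -> dict[float, list[tuple[int, float]]]:
    """First-passage times of one track at several passage lengths.

    The pairwise displacement matrix is computed once (in chunks over
    starting points, to bound memory) and scanned for every L.
    """
    pos = track.positions
    frames = track.frames
    n = len(pos)
    out: dict[float, list[tuple[int, float]]] = {L: [] for L in L_set}
    later = np.arange(n)[None, :]
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        diff = pos[None, a:b, :] - pos[:, None, :]  # (n, b-a, 2)
        d = np.linalg.norm(diff, axis=2).T  # (b-a, n); row i-a, col j
        future = later > np.arange(a, b)[:, None]
        for L in L_set:
            hits = (d >= L - _EPS) & future
            first = np.argmax(hits, axis=1)
            valid = hits[np.arange(b - a), first]
            bucket = out[L]
            for k in np.flatnonzero(valid):
                i = a + k
                t = (frames[first[k]] - frames[i]) * frame_interval
                bucket.append((int(i), float(t)))
    return out


def first_passage_times(
    track: Track, L: float, frame_interval: float
) -> list[tuple[int, float]]:
    """First-passage times of one track at passage length L.

    Returns (T_index, t_seconds) for every starting time point with a
    qualifying lag; starts that never reach displacement L contribute no
    passage (but still count toward the time-point total kept by the
    caller).
    """
    if L <= 0:
        raise ValueError(f"L must be positive, got {L}")
    return _first_passages_multi(track, [L], frame_interval)[L]


def first_passage_times_bruteforce(
    track: Track, L: float, frame_interval: float
) -> list[tuple[int, float]]:
    """Literal double-loop first-passage scan (the test oracle)."""
    pos = track.positions
    frames = track.frames
    n = len(pos)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            if (dx * dx + dy * dy) ** 0.5 >= L - _EPS:
                out.append((i, (frames[j] - frames[i]) * frame_interval))
                break
    return out


def fpp_distribution(
    tracks: list[Track],
    geom: AcquisitionGeometry,
    L_set=DEFAULT_L_SET,
    speed_bins: np.ndarray | None = None,
) -> dict[float, FPPResult]:
    """Pooled, normalized first-passage distributions for each L.

    Passages from all tracks are pooled; binned by speed u = L/t; and
    normalized by the pooled number of time points, so the per-L total
    probability is passages / time points and never exceeds 1.  An L at
    which no passage occurs is still reported, with a zero distribution.
    """
    L_set = list(L_set)
    if not L_set:
        raise ValueError("L_set must be non-empty")
    if any(b <= a for a, b in zip(L_set, L_set[1:])):
        raise ValueError("L_set must be strictly increasing")
    if speed_bins is None:
        speed_bins = default_speed_bins()
    total_time_points = sum(len(t) for t in tracks)
    dt = geom.frame_interval
    pooled: dict[float, list[tuple[int, float]]] = {L: [] for L in L_set}
    for track in tracks:
        per_track = _first_passages_multi(track, L_set, dt)
        for L in L_set:
            pooled[L].extend(per_track[L])
    results: dict[float, FPPResult] = {}
    for L in L_set:
        starts = [p[0] for p in pooled[L]]
        times_arr = np.asarray([p[1] for p in pooled[L]], dtype=float)
        speeds = L / times_arr if len(times_arr) else np.empty(0)
        counts, _ = np.histogram(speeds, bins=speed_bins)
        prob = counts / total_time_points if total_time_points else counts.astype(float)
        results[L] = FPPResult(
            L=L,
            start_frames=np.asarray(starts, dtype=int),
            times=times_arr,
            speeds=speeds,
            total_time_points=total_time_points,
            bin_edges=speed_bins,
            bin_probability=prob,
        )
    return results


def mean_passage_speed(results: dict[float, FPPResult]) -> pd.DataFrame:
    """Unweighted mean passage speed per L; zero-passage Ls are absent."""
    rows = [
        {"L": r.L, "n_passages": r.n_passages, "mean_speed": float(r.speeds.mean())}
        for r in results.values()
        if r.n_passages > 0
    ]
    return pd.DataFrame(rows, columns=["L", "n_passages", "mean_speed"])


def static_error(
    fixed_tracks: list[Track],
    geom: AcquisitionGeometry,
    L_set=DEFAULT_L_SET,
    reference: dict[float, FPPResult] | None = None,
) -> pd.DataFrame:
    """Per-L passage fraction of noise-only (fixed-cell) tracks.

    ``passage_fraction`` is passages per observed time point.  When a
    reference condition's results are supplied, the noise fraction is
    also expressed as a percentage of the reference's passage rate at the
    same L — the static-error estimate for that condition.
    """
    results = fpp_distribution(fixed_tracks, geom, L_set=L_set)
    rows = []
    for L, r in results.items():
        row = {"L": L, "n_passages": r.n_passages, "passage_fraction": r.passage_fraction}
        if reference is not None and L in reference:
            ref_frac = reference[L].passage_fraction
            row["pct_of_reference"] = (
                100.0 * r.passage_fraction / ref_frac if ref_frac > 0 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
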