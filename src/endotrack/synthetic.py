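"""Ground-truthed simulation of motor-driven organelle motion.

The generator emulates the statistical structure of early-endosome
motility seen in high-speed (28 frames/s) fluorescence movies: particles
switch stochastically between stationary *rests* and directed *runs*;
each run is a chain of constant-speed straight segments whose speed is
redrawn segment by segment (up to ~8 µm/s) while the distance covered by
a segment stays around 1.4 µm on average, independent of speed.  Runs
point towards or away from the cell centre (roughly radial microtubules)
with a configurable inward bias.  Observed positions are the true
positions plus i.i.d. Gaussian localization noise, and fixed-cell
(noise-only) fixtures provide the static-error control.

Everything is driven by explicit seeds: identical seeds give bit-identical
tracks, ground truth, and rendered movies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import AcquisitionGeometry
from .track_ops import Track

__all__ = [
    "Exponential",
    "LogUniform",
    "Uniform",
    "Constant",
    "MotionModelParams",
    "GroundTruth",
    "simulate_track",
    "simulate_population",
    "render_movie",
    "fixed_cell_fixture",
    "random_walk_tracks",
    "piecewise_speed_series",
    "control_params",
    "inhibited_params",
    "params_for_run_fraction",
    "run_fraction_expectation",
    "run_fraction_std",
]


# ---------------------------------------------------------------------------
# sampling laws


@dataclass(frozen=True)
class Exponential:
    """Exponential law with optional lower truncation (shifted support)."""

    mean: float
    low: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.mean) or self.mean <= 0:
            raise ValueError(f"Exponential mean must be positive, got {self.mean}")
        if self.low < 0 or self.low >= self.mean * 10:
            raise ValueError(f"invalid truncation point {self.low}")

    def sample(self, rng: np.random.Generator, size=None):
        # shifted exponential: low + Exp(mean - low) keeps the stated mean
        scale = max(self.mean - self.low, 1e-12)
        return self.low + rng.exponential(scale, size=size)


@dataclass(frozen=True)
class LogUniform:
    """Log-uniform law on [low, high]; right-skewed, many slow draws."""

    low: float
    high: float

    def __post_init__(self):
        if not (0 < self.low < self.high) or not np.isfinite(self.high):
            raise ValueError(f"LogUniform requires 0 < low < high, got {self}")

    def sample(self, rng: np.random.Generator, size=None):
        return np.exp(rng.uniform(math.log(self.low), math.log(self.high), size=size))


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __post_init__(self):
        if not (self.low < self.high):
            raise ValueError(f"Uniform requires low < high, got {self}")

    def sample(self, rng: np.random.Generator, size=None):
        return rng.uniform(self.low, self.high, size=size)


@dataclass(frozen=True)
class Constant:
    value: float

    def sample(self, rng: np.random.Generator, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


# ---------------------------------------------------------------------------
# model parameters


@dataclass(frozen=True)
class MotionModelParams:
    """Parameters of the run/rest motion model.

    Durations are exponential (memoryless switching); segment speeds are
    log-uniform on (0.3, 8] µm/s by default and segment distances
    exponential with mean 1.4 µm truncated below at 0.1 µm.  A run keeps
    one direction; only the speed changes between its segments.
    ``run_probability`` scales how often a scheduled run actually occurs
    (0 gives an always-resting particle), and ``max_run_distance`` caps
    the total distance of a single run (used for inhibited-motility
    conditions).
    """

    mean_rest_duration: float = 2.5  # s
    mean_run_duration: float = 0.7  # s  (~22% of time running by default)
    segment_speed_law: object = Uniform(0.5, 8.0)  # µm/s
    segment_distance_law: object = Exponential(1.4, low=0.1)  # µm
    localization_noise_sigma: float = 0.020  # µm per coordinate
    inward_fraction: float = 0.5
    run_probability: float = 1.0
    angle_jitter_deg: float = 15.0
    max_run_distance: float | None = None  # µm, per run
    seed: int = 0

    def __post_init__(self):
        for name in ("mean_rest_duration", "mean_run_duration"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be positive and finite, got {v}")
        if not np.isfinite(self.localization_noise_sigma) or self.localization_noise_sigma < 0:
            raise ValueError(f"localization_noise_sigma must be >= 0")
        if not 0.0 <= self.inward_fraction <= 1.0:
            raise ValueError(f"inward_fraction must be in [0, 1], got {self.inward_fraction}")
        if not 0.0 <= self.run_probability <= 1.0:
            raise ValueError(f"run_probability must be in [0, 1], got {self.run_probability}")
        if self.max_run_distance is not None and self.max_run_distance <= 0:
            raise ValueError("max_run_distance must be positive or None")


def run_fraction_expectation(params: MotionModelParams) -> float:
    """Stationary fraction of time spent running (alternating renewal)."""
    mr, mn = params.mean_rest_duration, params.mean_run_duration
    return params.run_probability * mn / (mr + mn)


def run_fraction_std(params: MotionModelParams, total_time: float) -> float:
    """Asymptotic std of the empirical run-time fraction over ``total_time``.

    For exponential rest/run durations the time-average fraction is
    asymptotically normal with variance 2 µr² µn² / (µr + µn)³ / T.
    """
    mr, mn = params.mean_rest_duration, params.mean_run_duration
    var = 2.0 * mr**2 * mn**2 / (mr + mn) ** 3 / total_time
    return math.sqrt(var)


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class PieceTruth:
    """One constant-velocity piece of the noiseless construction."""

    t0: float
    t1: float
    kind: str  # "run" | "rest"
    speed: float  # µm/s (0 for rests)
    direction: np.ndarray  # unit vector, zeros for rests

    @property
    def duration(self) -> float:
        return self.t1 - self.t0


@dataclass
class GroundTruth:
    """Noiseless construction of a simulated track.

    ``labels`` holds the run/rest state of every frame; ``change_points``
    are the frames nearest to every piece boundary at which state, speed
    or direction changes; ``pieces`` is the full continuous-time event
    list and ``true_positions`` the noiseless per-frame positions in µm.
    """

    labels: np.ndarray
    change_points: np.ndarray
    pieces: list[PieceTruth]
    true_positions: np.ndarray

    @property
    def run_mask(self) -> np.ndarray:
        return self.labels == "run"

    @property
    def run_time_fraction(self) -> float:
        return float(np.mean(self.run_mask))

    def run_segments(self) -> list[tuple[int, int, float]]:
        """(start_frame, end_frame, speed) for run pieces, frame-resolved."""
        n = len(self.labels)
        out = []
        for p in self.pieces:
            if p.kind != "run":
                continue
            # frames whose sample time falls inside the piece
            f0 = int(math.ceil(p.t0 * self._frame_rate - 1e-9))
            f1 = int(math.floor(p.t1 * self._frame_rate + 1e-9))
            f0, f1 = max(f0, 0), min(f1, n - 1)
            if f1 > f0:
                out.append((f0, f1, p.speed))
        return out

    _frame_rate: float = 28.0


# ---------------------------------------------------------------------------
# track simulation


def _run_direction(
    rng: np.random.Generator,
    pos: np.ndarray,
    geom: AcquisitionGeometry,
    params: MotionModelParams,
) -> np.ndarray:
    centre = np.asarray(geom.cell_centre, dtype=float)
    radial = centre - pos
    norm = np.linalg.norm(radial)
    inward = rng.random() < params.inward_fraction
    if norm < 1e-9:
        theta = rng.uniform(0, 2 * math.pi)
    else:
        base = radial / norm if inward else -radial / norm
        theta = math.atan2(base[1], base[0])
        theta += math.radians(params.angle_jitter_deg) * rng.standard_normal()
    return np.array([math.cos(theta), math.sin(theta)])


def _build_pieces(
    params: MotionModelParams,
    geom: AcquisitionGeometry,
    total_time: float,
    start: np.ndarray,
    rng: np.random.Generator,
) -> list[PieceTruth]:
    pieces: list[PieceTruth] = []
    t = 0.0
    pos = start.astype(float).copy()
    zero = np.zeros(2)
    # stationary initial state so time-averages are unbiased
    in_rest = rng.random() < params.mean_rest_duration / (
        params.mean_rest_duration + params.mean_run_duration
    )
    while t < total_time:
        if in_rest:
            d = rng.exponential(params.mean_rest_duration)
            pieces.append(PieceTruth(t, t + d, "rest", 0.0, zero))
            t += d
            in_rest = False
            continue
        run_time = rng.exponential(params.mean_run_duration)
        if rng.random() >= params.run_probability:
            pieces.append(PieceTruth(t, t + run_time, "rest", 0.0, zero))
            t += run_time
            in_rest = True
            continue
        direction = _run_direction(rng, pos, geom, params)
        remaining = run_time
        dist_used = 0.0
        cap = params.max_run_distance
        while remaining > 1e-12 and (cap is None or dist_used < cap - 1e-12):
            speed = float(params.segment_speed_law.sample(rng))
            if not np.isfinite(speed) or speed <= 0:
                raise ValueError(f"segment speed law produced invalid speed {speed}")
            seg_dist = float(params.segment_distance_law.sample(rng))
            if cap is not None:
                seg_dist = min(seg_dist, cap - dist_used)
            dur = seg_dist / speed
            if dur > remaining:
                dur = remaining
                seg_dist = speed * dur
            pieces.append(PieceTruth(t, t + dur, "run", speed, direction))
            pos = pos + speed * dur * direction
            t += dur
            remaining -= dur
            dist_used += seg_dist
        if remaining > 1e-12:
            # run stopped early at the distance cap; idle until switching
            pieces.append(PieceTruth(t, t + remaining, "rest", 0.0, zero))
            t += remaining
        in_rest = True
    return pieces


def simulate_track(
    params: MotionModelParams,
    geom: AcquisitionGeometry,
    n_frames: int,
    start: np.ndarray | None = None,
    seed: int | None = None,
    track_id: int = 0,
) -> tuple[Track, GroundTruth]:
    """Simulate one particle track with full ground truth.

    Returns the observed :class:`Track` (true positions plus Gaussian
    localization noise) and the :class:`GroundTruth` of its construction.
    ``seed`` overrides ``params.seed`` when given.
    """
    if n_frames < 2:
        raise ValueError(f"n_frames must be >= 2, got {n_frames}")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    if start is None:
        w, h = geom.field_size
        start = np.array([w / 2.0, h / 2.0])
    start = np.asarray(start, dtype=float)

    dt = geom.frame_interval
    total_time = (n_frames - 1) * dt
    pieces = _build_pieces(params, geom, total_time + dt, start, rng)

    # positions at piece starts
    piece_start_pos = np.empty((len(pieces), 2))
    p = start.copy()
    for i, pc in enumerate(pieces):
        piece_start_pos[i] = p
        p = p + pc.speed * pc.duration * pc.direction

    t_frames = np.arange(n_frames) * dt
    ends = np.array([pc.t1 for pc in pieces])
    idx = np.minimum(np.searchsorted(ends, t_frames, side="right"), len(pieces) - 1)
    speeds = np.array([pc.speed for pc in pieces])
    dirs = np.array([pc.direction for pc in pieces])
    t0s = np.array([pc.t0 for pc in pieces])
    kinds = np.array([pc.kind for pc in pieces])

    true_pos = piece_start_pos[idx] + (speeds[idx] * (t_frames - t0s[idx]))[:, None] * dirs[idx]
    labels = kinds[idx].copy()

    change_points = _change_point_frames(pieces, dt, n_frames)
    noise = rng.normal(0.0, params.localization_noise_sigma, size=(n_frames, 2))
    observed = true_pos + noise

    track = Track(track_id=track_id, frames=np.arange(n_frames), positions=observed)
    truth = GroundTruth(
        labels=labels,
        change_points=change_points,
        pieces=pieces,
        true_positions=true_pos,
        _frame_rate=geom.frame_rate,
    )
    return track, truth


def _change_point_frames(pieces: list[PieceTruth], dt: float, n_frames: int) -> np.ndarray:
    cps = []
    for prev, cur in zip(pieces[:-1], pieces[1:]):
        changed = (
            prev.kind != cur.kind
            or abs(prev.speed - cur.speed) > 1e-12
            or not np.allclose(prev.direction, cur.direction)
        )
        if not changed:
            continue
        f = int(round(cur.t0 / dt))
        if 0 < f < n_frames - 1:
            cps.append(f)
    return np.unique(cps).astype(int)


def simulate_population(
    params: MotionModelParams,
    geom: AcquisitionGeometry,
    n_tracks: int,
    n_frames: int,
    seed: int | None = None,
) -> list[tuple[Track, GroundTruth]]:
    """Independent tracks with start points spread over the field.

    Per-track seeds are spawned deterministically from the master seed, so
    a fixed master seed reproduces the whole population bit-for-bit.
    """
    if n_tracks < 1:
        raise ValueError(f"n_tracks must be >= 1, got {n_tracks}")
    master = params.seed if seed is None else seed
    ss = np.random.SeedSequence(master)
    start_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(n_tracks)
    w, h = geom.field_size
    margin = 0.15
    out = []
    for i in range(n_tracks):
        start = np.array(
            [
                start_rng.uniform(margin * w, (1 - margin) * w),
                start_rng.uniform(margin * h, (1 - margin) * h),
            ]
        )
        t, g = simulate_track(
            params,
            geom,
            n_frames,
            start=start,
            seed=child_seeds[i],
            track_id=i,
        )
        out.append((t, g))
    return out


# ---------------------------------------------------------------------------
# fixtures and auxiliary generators


def fixed_cell_fixture(
    n_particles: int,
    sigma: float,
    n_frames: int,
    geom: AcquisitionGeometry,
    seed: int = 0,
) -> list[Track]:
    """Noise-only tracks emulating a fixed (chemically immobilized) cell.

    True positions are constant; observed positions jitter with i.i.d.
    Gaussian noise of the given sigma (µm per coordinate).  This is the
    static-error control used to calibrate rest thresholds and
    first-passage noise floors.
    """
    if sigma < 0 or not np.isfinite(sigma):
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if n_particles < 1 or n_frames < 2:
        raise ValueError("need n_particles >= 1 and n_frames >= 2")
    rng = np.random.default_rng(seed)
    w, h = geom.field_size
    tracks = []
    for i in range(n_particles):
        centre = np.array([rng.uniform(0.15 * w, 0.85 * w), rng.uniform(0.15 * h, 0.85 * h)])
        obs = centre[None, :] + rng.normal(0.0, sigma, size=(n_frames, 2))
        tracks.append(Track(track_id=i, frames=np.arange(n_frames), positions=obs))
    return tracks


def random_walk_tracks(
    n_tracks: int,
    n_frames: int,
    step_sigma: float,
    geom: AcquisitionGeometry,
    seed: int = 0,
) -> list[Track]:
    """Pure diffusion controls: Gaussian increments of sd ``step_sigma`` µm."""
    rng = np.random.default_rng(seed)
    w, h = geom.field_size
    tracks = []
    for i in range(n_tracks):
        start = np.array([w / 2, h / 2])
        steps = rng.normal(0.0, step_sigma, size=(n_frames - 1, 2))
        pos = np.vstack([start, start + np.cumsum(steps, axis=0)])
        tracks.append(Track(track_id=i, frames=np.arange(n_frames), positions=pos))
    return tracks


def piecewise_speed_series(
    geom: AcquisitionGeometry,
    n_segments: int = 4,
    speed_range: tuple[float, float] = (0.5, 8.0),
    seg_frames: tuple[int, int] = (10, 40),
    noise_sigma: float = 0.020,
    min_speed_ratio: float = 1.5,
    sign_flip_p: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """A 1-D displacement curve x(T) made of constant-slope pieces.

    Emulates the displacement-vs-time curve of a long directed track:
    consecutive pieces change slope clearly (speed ratio >=
    ``min_speed_ratio`` unless the sign flips) so that a slope change is
    identifiable above localization noise.  Returns (frames, x_noisy,
    truth) where truth holds the exact change points, speeds and signed
    slopes.
    """
    rng = np.random.default_rng(seed)
    lo, hi = speed_range
    slopes = []
    sign = 1.0
    for _ in range(n_segments):
        for _ in range(200):
            v = rng.uniform(lo, hi)
            s = sign if rng.random() >= sign_flip_p or not slopes else -np.sign(slopes[-1])
            cand = v * s
            if not slopes:
                break
            prev = slopes[-1]
            if np.sign(cand) != np.sign(prev):
                break
            ratio = max(abs(cand), abs(prev)) / min(abs(cand), abs(prev))
            if ratio >= min_speed_ratio:
                break
        slopes.append(cand)
        sign = np.sign(cand)
    lengths = rng.integers(seg_frames[0], seg_frames[1] + 1, size=n_segments)
    dt = geom.frame_interval
    x = [0.0]
    change_points = []
    for slope, m in zip(slopes, lengths):
        for _ in range(int(m)):
            x.append(x[-1] + slope * dt)
        change_points.append(len(x) - 1)
    change_points = np.array(change_points[:-1], dtype=int)
    x = np.asarray(x)
    frames = np.arange(len(x))
    x_noisy = x + rng.normal(0.0, noise_sigma, size=len(x))
    truth = {
        "change_points": change_points,
        "slopes": np.asarray(slopes),
        "speeds": np.abs(slopes),
        "lengths": lengths,
        "x_true": x,
    }
    return frames, x_noisy, truth


# ---------------------------------------------------------------------------
# movie rendering


def render_movie(
    tracks: list[Track],
    geom: AcquisitionGeometry,
    psf_sigma: float = 1.5,
    peak_snr: float | None = 10.0,
    background: float | tuple = 10.0,
    amplitude: float = 100.0,
    n_frames: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render tracks into a synthetic fluorescence image stack.

    Each particle becomes an isotropic Gaussian spot of width ``psf_sigma``
    pixels and peak amplitude ``amplitude`` above background.  Noise is
    Poisson, with the photon gain chosen so that the signal-to-noise ratio
    at the spot peak equals ``peak_snr`` (``None`` disables noise).
    ``background`` is either a constant or ``("ramp", low, high)`` for a
    linear intensity ramp across the field.  Returns the float stack and a
    per-frame truth table of rendered positions.
    """
    if psf_sigma <= 0:
        raise ValueError(f"psf_sigma must be positive, got {psf_sigma}")
    shape = geom.image_shape()
    if n_frames is None:
        n_frames = max((int(t.frames[-1]) + 1 for t in tracks), default=1)

    if isinstance(background, tuple):
        tag, lo, hi = background
        if tag != "ramp":
            raise ValueError(f"unknown background {background!r}")
        bg = np.tile(np.linspace(lo, hi, shape[1])[None, :], (shape[0], 1))
    else:
        bg = np.full(shape, float(background))

    stack = np.tile(bg[None, :, :], (n_frames, 1, 1))
    half = int(math.ceil(4 * psf_sigma))
    truth_rows = []
    w_um, h_um = geom.field_size
    for t in tracks:
        for frame, pos in zip(t.frames, t.positions):
            x, y = pos
            if not (0 <= x <= w_um and 0 <= y <= h_um):
                raise ValueError(
                    f"track {t.track_id} frame {frame}: position ({x:.3f}, {y:.3f}) µm "
                    f"outside field {geom.field_size}"
                )
            col = x * geom.pixel_scale
            row = y * geom.pixel_scale
            r0, r1 = int(math.floor(row)) - half, int(math.floor(row)) + half + 1
            c0, c1 = int(math.floor(col)) - half, int(math.floor(col)) + half + 1
            r0c, r1c = max(r0, 0), min(r1, shape[0])
            c0c, c1c = max(c0, 0), min(c1, shape[1])
            if r0c >= r1c or c0c >= c1c:
                continue
            rr = np.arange(r0c, r1c)
            cc = np.arange(c0c, c1c)
            g = np.exp(
                -((rr[:, None] - row) ** 2 + (cc[None, :] - col) ** 2) / (2 * psf_sigma**2)
            )
            stack[int(frame), r0c:r1c, c0c:c1c] += amplitude * g
            truth_rows.append(
                {
                    "track_id": t.track_id,
                    "frame": int(frame),
                    "x_um": x,
                    "y_um": y,
                    "x_px": col,
                    "y_px": row,
                }
            )

    if peak_snr is not None:
        rng = np.random.default_rng(seed)
        gain = peak_snr**2 / amplitude
        stack = rng.poisson(np.clip(stack, 0, None) * gain).astype(float) / gain

    truth = pd.DataFrame(truth_rows, columns=["track_id", "frame", "x_um", "y_um", "x_px", "y_px"])
    return stack.astype(np.float32), truth


# ---------------------------------------------------------------------------
# condition presets


def control_params(seed: int = 0) -> MotionModelParams:
    """Motile control condition: frequent runs, speeds up to 8 µm/s,
    occasional long (>9 µm) translocations."""
    return MotionModelParams(
        mean_rest_duration=2.5,
        mean_run_duration=1.5,
        segment_speed_law=Uniform(0.5, 8.0),
        segment_distance_law=Exponential(1.4, low=0.1),
        localization_noise_sigma=0.020,
        inward_fraction=0.5,
        seed=seed,
    )


def inhibited_params(seed: int = 0) -> MotionModelParams:
    """Motor-inhibited condition: rare, short, slow runs capped at 3 µm."""
    return MotionModelParams(
        mean_rest_duration=20.0,
        mean_run_duration=0.4,
        segment_speed_law=Uniform(0.3, 4.0),
        segment_distance_law=Exponential(1.4, low=0.1),
        localization_noise_sigma=0.020,
        inward_fraction=0.5,
        max_run_distance=3.0,
        seed=seed,
    )


def params_for_run_fraction(
    fraction: float,
    mean_run_duration: float = 5.0,
    seed: int = 0,
    **kwargs,
) -> MotionModelParams:
    """Parameters whose stationary run-time fraction equals ``fraction``.

    The mean run duration is held fixed (default 5 s, a persistent
    multi-micrometre translocation, several times the contour smoothing
    scale) and the mean rest duration derived, so that the run/rest
    classifier's finite smoothing window costs the same absolute time
    per run across conditions.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    mean_rest = mean_run_duration * (1 - fraction) / fraction
    return MotionModelParams(
        mean_rest_duration=mean_rest,
        mean_run_duration=mean_run_duration,
        seed=seed,
        **kwargs,
    )
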