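"""Track stitching, contour smoothing/coarsening, arc-length projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endotrack import AcquisitionGeometry, Track, build_contour, project_track, stitch
from endotrack.track_ops import DEFAULT_LPIX


def make_track(tid, frames, positions, **kw):
    return Track(track_id=tid, frames=np.asarray(frames), positions=np.asarray(positions, dtype=float), **kw)


def straight(tid, f0, n, x0, step=0.05, y=5.0):
    frames = np.arange(f0, f0 + n)
    xs = x0 + step * np.arange(n)
    return make_track(tid, frames, np.column_stack([xs, np.full(n, y)]))


class TestStitch:
    def test_admissible_gap_is_merged(self, geom):
        """End/start within 5 px (0.43 µm) and 10 frames -> one track."""
        a = straight(0, 0, 20, 0.0)
        gap_um = 3.0 / geom.pixel_scale
        b = straight(1, 30, 20, a.positions[-1, 0] + gap_um)
        out = stitch([a, b], pixel_scale=geom.pixel_scale)
        assert len(out) == 1
        assert out[0].source == "stitched"
        # gap frames are interpolated and flagged
        assert np.array_equal(out[0].frames, np.arange(0, 50))
        assert out[0].interpolated == frozenset(range(20, 30))

    def test_spatial_bound_exceeded_not_merged(self, geom):
        a = straight(0, 0, 20, 0.0)
        b = straight(1, 25, 20, a.positions[-1, 0] + 6.0 / geom.pixel_scale)
        assert len(stitch([a, b], pixel_scale=geom.pixel_scale)) == 2

    def test_temporal_bound_exceeded_not_merged(self, geom):
        a = straight(0, 0, 20, 0.0)
        b = straight(1, 20 + 15, 20, a.positions[-1, 0])  # 15-frame gap > 14
        assert len(stitch([a, b], pixel_scale=geom.pixel_scale)) == 2

    def test_three_fragments_chain_into_one(self, geom):
        """A track cut into 3 admissible pieces re-joins uniquely; the
        non-interpolated point count is preserved (brute-force pairwise
        gap search confirms exactly two admissible joins)."""
        full = straight(0, 0, 90, 0.0, step=0.02)
        pieces = [
            make_track(0, full.frames[:30], full.positions[:30]),
            make_track(1, full.frames[35:60], full.positions[35:60]),
            make_track(2, full.frames[64:90], full.positions[64:90]),
        ]
        admissible = 0
        for i, a in enumerate(pieces):
            for j, b in enumerate(pieces):
                if i == j:
                    continue
                fg = b.frames[0] - a.frames[-1]
                sg = np.linalg.norm(b.positions[0] - a.positions[-1]) * geom.pixel_scale
                if 1 <= fg <= 14 and sg <= 5:
                    admissible += 1
        assert admissible == 2
        out = stitch(pieces, pixel_scale=geom.pixel_scale)
        assert len(out) == 1
        merged = out[0]
        n_real = len(merged) - len(merged.interpolated)
        assert n_real == sum(len(p) for p in pieces)

    def test_stitching_is_idempotent(self, geom):
        rng = np.random.default_rng(3)
        tracks = []
        f = 0
        for tid in range(8):
            n = int(rng.integers(10, 30))
            tracks.append(straight(tid, f, n, rng.uniform(0, 5)))
            f += n + int(rng.integers(1, 20))
        once = stitch(tracks, pixel_scale=geom.pixel_scale)
        twice = stitch(once, pixel_scale=geom.pixel_scale)
        assert len(once) == len(twice)
        for t1, t2 in zip(once, twice):
            assert np.array_equal(t1.frames, t2.frames)
            assert np.allclose(t1.positions, t2.positions)


class TestBuildContour:
    def test_straight_track_vertices_collinear(self):
        track = straight(0, 0, 100, 0.0)
        contour = build_contour(track)
        v = contour.coarse_vertices
        assert not contour.degenerate
        spread = np.ptp(v[:, 1])
        assert spread < 1e-9
        assert contour.length >= track.net_displacement

    def test_smoothing_suppresses_jitter(self, rng):
        """20 nm jitter on a straight line: smoothed points deviate from
        the generating line by < 50 nm RMS."""
        n = 300
        xs = 0.03 * np.arange(n)
        pos = np.column_stack([xs, np.full(n, 2.0)]) + rng.normal(0, 0.020, (n, 2))
        contour = build_contour(make_track(0, np.arange(n), pos))
        dev = contour.smoothed_points[:, 1] - 2.0
        assert np.sqrt(np.mean(dev**2)) < 0.050

    def test_coincident_track_is_degenerate(self):
        pos = np.tile([3.0, 4.0], (50, 1))
        contour = build_contour(make_track(0, np.arange(50), pos))
        assert contour.degenerate
        assert np.all(contour.arc_positions == 0.0)

    def test_vertices_in_track_progress_order(self):
        track = straight(0, 0, 200, 0.0, step=0.04)
        contour = build_contour(track)
        x_of_vertices = contour.coarse_vertices[:, 0]
        assert np.all(np.diff(x_of_vertices) > 0)

    def test_requires_two_points(self):
        with pytest.raises(ValueError):
            build_contour(make_track(0, [0], [[1.0, 1.0]]))


def brute_force_projection(points, vertices):
    """Oracle: nearest point on a densely sampled polyline."""
    samples, arcs = [], []
    arc = 0.0
    for a, b in zip(vertices[:-1], vertices[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(seg / 0.002), 2)
        for t in np.linspace(0, 1, n, endpoint=False):
            samples.append(a + t * (b - a))
            arcs.append(arc + t * seg)
        arc += seg
    samples.append(vertices[-1])
    arcs.append(arc)
    samples = np.array(samples)
    arcs = np.array(arcs)
    out = []
    for p in points:
        d = np.linalg.norm(samples - p, axis=1)
        out.append(arcs[np.argmin(d)])
    return np.array(out)


class TestProjectTrack:
    def test_constant_speed_run_gives_linear_x(self, geom):
        v = 1.0
        n = 200
        t = np.arange(n) * geom.frame_interval
        pos = np.column_stack([5 + v * t, np.full(n, 5.0)])
        track = make_track(0, np.arange(n), pos)
        contour = build_contour(track)
        x = contour.arc_positions
        assert np.allclose(x, v * t, atol=v * geom.frame_interval + DEFAULT_LPIX)

    def test_vertex_point_maps_to_vertex_arc(self):
        track = straight(0, 0, 100, 0.0, step=0.05)
        contour = build_contour(track)
        verts = contour.coarse_vertices
        seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        arc = np.concatenate([[0], np.cumsum(seg)])
        # project the contour's own vertices (as a fake smoothed track)
        from endotrack.track_ops import SmoothedContour, project_track

        fake = SmoothedContour(track_id=0, smoothed_points=verts, coarse_vertices=verts)
        x = project_track(make_track(0, np.arange(len(verts)), verts), fake)
        assert np.allclose(x, arc - arc[0], atol=1e-9)

    def test_out_and_back_motion(self, geom):
        """2 µm out and 2 µm back along a straight path: max x ~ 2 µm,
        final x ~ 0; agrees with a brute-force dense projection."""
        step = 0.04
        fwd = np.arange(0, 2.0 + step, step)
        path = np.concatenate([fwd, fwd[::-1][1:]])
        pos = np.column_stack([3 + path, np.full(len(path), 3.0)])
        rng = np.random.default_rng(0)
        pos = pos + rng.normal(0, 0.01, pos.shape)
        track = make_track(0, np.arange(len(pos)), pos)
        contour = build_contour(track)
        x = contour.arc_positions
        # the apex is truncated by up to ~2 Lpix of smoothing/coarsening
        assert 2.0 - 2 * DEFAULT_LPIX < x.max() < 2.0 + 0.1
        assert abs(x[-1]) < 0.1
        # brute-force check is done in space: on a folded contour the two
        # overlapping limbs are arc-ambiguous, but the projected FOOT of
        # every point must coincide with the dense-scan nearest point
        verts = contour.coarse_vertices
        seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
        arc_v = np.concatenate([[0.0], np.cumsum(seg)])
        oracle_arcs = brute_force_projection(contour.smoothed_points, verts)

        def foot(arc):
            fx = np.interp(arc, arc_v, verts[:, 0])
            fy = np.interp(arc, arc_v, verts[:, 1])
            return np.array([fx, fy])

        x_abs = x + oracle_arcs[0]  # undo the first-frame-zero shift
        for xi, oi in zip(x_abs, oracle_arcs):
            assert np.linalg.norm(foot(xi) - foot(oi)) < 0.1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_projection_contraction_bound(self, seed):
        """|x(T+1) - x(T)| <= raw inter-frame displacement + 2 Lpix,
        except at the rare frames where lock on a limb of a
        self-approaching contour is lost and globally re-acquired."""
        rng = np.random.default_rng(seed)
        n = 60
        steps = rng.normal(0, 0.08, (n - 1, 2))
        pos = np.vstack([[5.0, 5.0], [5.0, 5.0] + np.cumsum(steps, axis=0)])
        track = make_track(0, np.arange(n), pos)
        contour = build_contour(track)
        dx = np.abs(np.diff(contour.arc_positions))
        raw = np.linalg.norm(np.diff(track.positions, axis=0), axis=1)
        violations = dx > raw + 2 * DEFAULT_LPIX + 1e-9
        assert violations.mean() <= 0.02

    def test_contraction_strict_on_directed_track(self, geom):
        """On a non-self-approaching contour the bound holds exactly."""
        t = np.arange(400) * geom.frame_interval
        pos = np.column_stack([5 + 1.5 * t, 5 + 0.5 * np.sin(0.5 * t)])
        pos = pos + np.random.default_rng(0).normal(0, 0.02, pos.shape)
        track = make_track(0, np.arange(400), pos)
        contour = build_contour(track)
        dx = np.abs(np.diff(contour.arc_positions))
        raw = np.linalg.norm(np.diff(pos, axis=0), axis=1)
        assert np.all(dx <= raw + 2 * DEFAULT_LPIX + 1e-9)
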