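"""File I/O: delimited track tables, TIFF stacks, ground-truth sidecars.

The interchange format between all pipeline stages is a delimited track
table with columns ``track_id, frame, x_px, y_px, intensity`` so that
users can enter the pipeline with third-party tracking output.  Tables
store pixel coordinates; conversion to micrometres happens on read using
the acquisition geometry.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import AcquisitionGeometry
from .segmentation import MotionAnnotation
from .synthetic import GroundTruth
from .track_ops import Track

__all__ = [
    "read_tracks",
    "write_tracks",
    "read_movie",
    "write_movie",
    "write_ground_truth",
    "read_ground_truth_labels",
    "write_annotations",
]

TRACK_COLUMNS = ["track_id", "frame", "x_px", "y_px", "intensity"]


def write_tracks(path, tracks: list[Track], geom: AcquisitionGeometry) -> None:
    """Write tracks as a delimited table (pixel units)."""
    rows = []
    for t in tracks:
        px = geom.um_to_px(t.positions)
        inten = t.intensity if t.intensity is not None else np.zeros(len(t))
        for k in range(len(t)):
            rows.append(
                {
                    "track_id": t.track_id,
                    "frame": int(t.frames[k]),
                    "x_px": px[k, 0],
                    "y_px": px[k, 1],
                    "intensity": float(inten[k]),
                }
            )
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def read_tracks(path, geom: AcquisitionGeometry) -> list[Track]:
    """Parse a delimited track table into Track objects (micrometres).

    Raises descriptive errors for missing columns, non-numeric cells,
    duplicated (track_id, frame) pairs and non-monotone frames.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"track table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    for col in TRACK_COLUMNS[:4]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: non-numeric value in column '{col}' at line {line}")
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise ValueError(f"{path}: missing value in column '{col}' at line {line}")
        df[col] = coerced
    dup = df.duplicated(subset=["track_id", "frame"])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"{path}: duplicated (track_id, frame) = "
            f"({int(row.track_id)}, {int(row.frame)}) at line {int(dup.idxmax()) + 2}"
        )
    if "intensity" not in df.columns:
        df["intensity"] = 0.0
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=int)
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"{path}: track {tid} has non-monotone frames")
        pos_px = g[["x_px", "y_px"]].to_numpy(dtype=float)
        tracks.append(
            Track(
                track_id=int(tid),
                frames=frames,
                positions=geom.px_to_um(pos_px),
                intensity=g["intensity"].to_numpy(dtype=float),
            )
        )
    return tracks


def write_movie(path, stack: np.ndarray) -> None:
    """Write a multi-frame TIFF stack."""
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32), photometric="minisblack")


def read_movie(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, :, :]
    return stack


def write_ground_truth(path, truths: list[tuple[int, GroundTruth]]) -> None:
    """Sidecar table of per-frame state labels and true positions."""
    rows = []
    for tid, g in truths:
        cps = set(int(c) for c in g.change_points)
        for f, (label, pos) in enumerate(zip(g.labels, g.true_positions)):
            rows.append(
                {
                    "track_id": tid,
                    "frame": f,
                    "state": label,
                    "x_true_um": pos[0],
                    "y_true_um": pos[1],
                    "is_change_point": int(f in cps),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_ground_truth_labels(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(tid): g.sort_values("frame")["state"].to_numpy()
        for tid, g in df.groupby("track_id")
    }


def write_annotations(path, annotations: list[MotionAnnotation]) -> None:
    """Interval table of run/rest annotations."""
    rows = []
    for ann in annotations:
        for iv in ann.intervals:
            rows.append(
                {
                    "track_id": ann.track_id,
                    "movie_id": ann.movie_id,
                    "label": iv.label,
                    "start_frame": iv.start,
                    "end_frame": iv.end,
                    "displacement_um": iv.displacement,
                    "rate_um_per_s": iv.rate,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
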