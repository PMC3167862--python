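"""Pipeline configuration: geometry, thresholds, and derived constants.

All defaults mirror the analysis constants of a 28 frames/s, 11.72
pixels/µm acquisition: the rest window is 14 frames (0.5 s), the rest
displacement one pixel (85 nm), and the implied minimum run rate
0.17 µm/s.  Configs round-trip through YAML and validate before any
pipeline stage runs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .geometry import AcquisitionGeometry

__all__ = ["PipelineConfig", "derived_thresholds", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    # geometry
    frame_rate: float = 28.0
    pixel_scale: float = 11.72
    cell_centre: tuple[float, float] = (25.0, 25.0)
    field_size: tuple[float, float] = (50.0, 50.0)
    # thresholds
    rest_disp_um: float = 0.085
    rest_frames: int = 14
    min_run_rate_um_s: float = 0.17
    stitch_max_gap_px: float = 5.0
    stitch_max_gap_frames: int = 14
    lpix_um: float = 0.340
    long_track_um: float = 2.0
    fast_run_um_s: float = 5.0
    parse_min_frames: int = 3
    clear_displacement_um_s: float = 0.9
    # FPP
    L_set: tuple[float, ...] = (0.1, 0.5, 1.0, 3.0, 5.0, 7.0, 9.0)
    # synthetic input (used when no track table / movie is given)
    synthetic_condition: str | None = None  # "control" | "inhibited" | "fixed"
    n_tracks: int = 50
    n_frames: int = 500
    n_movies: int = 1
    seed: int = 0
    # paths
    input_tracks: str | None = None
    input_movie: str | None = None
    output_dir: str = "endotrack_out"
    make_plots: bool = False

    def __post_init__(self) -> None:
        positive = [
            "frame_rate", "pixel_scale", "rest_disp_um", "min_run_rate_um_s",
            "stitch_max_gap_px", "lpix_um", "long_track_um", "fast_run_um_s",
            "clear_displacement_um_s",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"config: {name} must be positive, got {getattr(self, name)}")
        for name in ["rest_frames", "stitch_max_gap_frames", "parse_min_frames",
                     "n_tracks", "n_frames", "n_movies"]:
            if getattr(self, name) < 1:
                raise ValueError(f"config: {name} must be >= 1, got {getattr(self, name)}")
        if list(self.L_set) != sorted(self.L_set) or min(self.L_set) <= 0:
            raise ValueError("config: L_set must be positive and increasing")
        if self.synthetic_condition not in (None, "control", "inhibited", "fixed"):
            raise ValueError(f"config: unknown synthetic_condition {self.synthetic_condition!r}")

    def geometry(self) -> AcquisitionGeometry:
        return AcquisitionGeometry(
            frame_rate=self.frame_rate,
            pixel_scale=self.pixel_scale,
            cell_centre=tuple(self.cell_centre),
            field_size=tuple(self.field_size),
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cell_centre"] = list(d["cell_centre"])
        d["field_size"] = list(d["field_size"])
        d["L_set"] = list(d["L_set"])
        return d


def derived_thresholds(geom: AcquisitionGeometry, rest_window_s: float = 0.5) -> dict:
    """Analysis constants implied by the acquisition geometry.

    At 28 frames/s the 0.5 s rest window is 14 frames; one pixel at
    11.72 px/µm is 85 nm; and a one-pixel displacement over the rest
    window implies a minimum run rate of 0.17 µm/s.
    """
    rest_window_frames = round(rest_window_s * geom.frame_rate)
    pixel_um = geom.pixel_size
    return {
        "rest_window_frames": int(rest_window_frames),
        "pixel_size_um": pixel_um,
        "pixel_size_nm": 1000.0 * pixel_um,
        "min_run_rate_um_s": pixel_um / rest_window_s,
    }


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "cell_centre" in data:
        data["cell_centre"] = tuple(data["cell_centre"])
    if "field_size" in data:
        data["field_size"] = tuple(data["field_size"])
    if "L_set" in data:
        data["L_set"] = tuple(data["L_set"])
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
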