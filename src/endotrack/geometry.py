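"""Acquisition geometry: how movie frames map onto physical space and time.

All analysis code works in micrometres and seconds; pixels appear only at
image I/O boundaries.  The default geometry matches a high-speed streaming
acquisition: 28 frames/s with 11.72 pixels per micrometre.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionGeometry"]


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Spatio-temporal calibration of a time-lapse acquisition.

    Parameters
    ----------
    frame_rate : float
        Frames per second (default 28).
    pixel_scale : float
        Pixels per micrometre (default 11.72, i.e. ~85 nm pixels).
    cell_centre : tuple of float
        (x, y) position of the cell centre in micrometres; the reference
        point for inward/outward track classification.
    field_size : tuple of float
        (width, height) of the imaged field in micrometres.
    """

    frame_rate: float = 28.0
    pixel_scale: float = 11.72
    cell_centre: tuple[float, float] = (25.0, 25.0)
    field_size: tuple[float, float] = (50.0, 50.0)

    def __post_init__(self) -> None:
        if not np.isfinite(self.frame_rate) or self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be positive, got {self.frame_rate}")
        if not np.isfinite(self.pixel_scale) or self.pixel_scale <= 0:
            raise ValueError(f"pixel_scale must be positive, got {self.pixel_scale}")
        w, h = self.field_size
        if w <= 0 or h <= 0:
            raise ValueError(f"field_size must be positive, got {self.field_size}")
        cx, cy = self.cell_centre
        if not (0 <= cx <= w and 0 <= cy <= h):
            raise ValueError(
                f"cell_centre {self.cell_centre} lies outside field {self.field_size}"
            )

    @property
    def frame_interval(self) -> float:
        """Seconds between consecutive frames (1 / frame_rate)."""
        return 1.0 / self.frame_rate

    @property
    def pixel_size(self) -> float:
        """Physical size of one pixel in micrometres (1 / pixel_scale)."""
        return 1.0 / self.pixel_scale

    def um_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        """Convert positions in micrometres to pixel units."""
        return np.asarray(xy_um, dtype=float) * self.pixel_scale

    def px_to_um(self, xy_px: np.ndarray) -> np.ndarray:
        """Convert positions in pixel units to micrometres."""
        return np.asarray(xy_px, dtype=float) / self.pixel_scale

    def image_shape(self) -> tuple[int, int]:
        """(rows, cols) of a rendered frame covering the full field."""
        w, h = self.field_size
        return (int(round(h * self.pixel_scale)), int(round(w * self.pixel_scale)))
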