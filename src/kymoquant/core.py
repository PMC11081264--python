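"""Core calibrated-image containers shared by every pipeline stage.

Coordinate conventions
----------------------
* Space along the neurite is measured in micrometres from the cell-body
  edge (``origin`` pixel column); anterograde motion increases the
  coordinate and is drawn rightward on kymographs.
* Movies are ``(frame, row, column)`` stacks; kymographs are
  ``(frame, column)`` grids with time increasing downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PixelGeometry", "Movie", "Kymograph", "ConfigurationError"]


class ConfigurationError(ValueError):
    """Invalid acquisition geometry or simulation configuration."""


@dataclass(frozen=True)
class PixelGeometry:
    """Acquisition calibration of a line-scan movie.

    Parameters
    ----------
    pixel_size : float
        Spatial calibration, micrometres per pixel.
    frame_interval : float
        Time between frames, seconds (3 fps -> 1/3 s).
    n_frames : int
        Number of frames in the movie.
    n_px : int
        Spatial pixels along the neurite.
    line_width_px : int
        Transverse width (rows) of the imaged line.
    """

    pixel_size: float = 0.126
    frame_interval: float = 1.0 / 3.0
    n_frames: int = 540
    n_px: int = 480
    line_width_px: int = 5

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ConfigurationError("pixel_size and frame_interval must be positive")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.n_px < 10:
            raise ConfigurationError("n_px must be >= 10")
        if self.line_width_px < 1:
            raise ConfigurationError("line_width_px must be >= 1")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval

    @property
    def length_um(self) -> float:
        return self.n_px * self.pixel_size


@dataclass
class Movie:
    """A calibrated single-channel ``(t, y, x)`` intensity stack."""

    data: np.ndarray
    geometry: PixelGeometry
    channel: str = "A"
    origin: int = 0
    orientation: int = 1  # +1: distance from cell body increases with column

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("movie data must be (frame, row, column)")
        t, y, x = self.data.shape
        g = self.geometry
        if t != g.n_frames or y != g.line_width_px or x != g.n_px:
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with geometry "
                f"({g.n_frames}, {g.line_width_px}, {g.n_px})"
            )
        if not 0 <= self.origin < g.n_px:
            raise ValueError("origin must lie within [0, n_px)")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def col_to_um(self, col: np.ndarray | float) -> np.ndarray | float:
        """Column index -> micrometres from the cell-body edge."""
        return (np.asarray(col) - self.origin) * self.geometry.pixel_size * self.orientation

    def um_to_col(self, x_um: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(x_um) / self.geometry.pixel_size * self.orientation + self.origin


@dataclass
class Kymograph:
    """Space-time image: rows are frames (time downward), columns are space."""

    data: np.ndarray
    geometry: PixelGeometry
    channel: str = "A"
    origin: int = 0
    orientation: int = 1
    time_offset_s: float = 0.0
    sync_group: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be (frame, column)")
        if self.data.shape != (self.geometry.n_frames, self.geometry.n_px):
            raise ValueError("kymograph shape inconsistent with geometry")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def row_to_s(self, row: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(row) * self.geometry.frame_interval + self.time_offset_s

    def col_to_um(self, col: np.ndarray | float) -> np.ndarray | float:
        return (np.asarray(col) - self.origin) * self.geometry.pixel_size * self.orientation

    def um_to_col(self, x_um: np.ndarray | float) -> np.ndarray | float:
        return np.asarray(x_um) / self.geometry.pixel_size * self.orientation + self.origin

    def copy(self) -> "Kymograph":
        return replace(self, data=self.data.copy())
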