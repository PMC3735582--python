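"""Core containers shared by all pipeline stages.

Coordinate convention (used everywhere in the package): physical coordinates
are 0-based pixel-center, ``x = column * pixel_size``, ``y = row * pixel_size``,
both in millimetres. All CSV output is in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "ChannelVolume",
    "LineProfile",
    "ProfileEnsemble",
    "CellPoints",
    "DensityGrid",
    "PunctateMask",
    "BiasField",
    "Sinogram",
]


@dataclass
class ChannelVolume:
    """A single-channel scalar image grid (2D slice or 3D stack).

    Parameters
    ----------
    data:
        Intensity array, float. 2D arrays are (row, col); 3D are
        (slice, row, col).
    pixel_size:
        In-plane pixel size in mm/pixel (isotropic).
    channel:
        Free-text channel label, e.g. ``"stain"`` or ``"auto"``.
    incubation_time:
        Incubation duration in hours, if the image belongs to a timed
        penetration experiment; otherwise ``None``.
    """

    data: np.ndarray
    pixel_size: float
    channel: str = ""
    incubation_time: float | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3D data, got ndim={self.data.ndim}")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def iter_slices(self):
        """Yield (slice_index, 2D array) pairs; a 2D volume yields itself once."""
        if self.data.ndim == 2:
            yield 0, self.data
        else:
            for i in range(self.data.shape[0]):
                yield i, self.data[i]


@dataclass
class LineProfile:
    """Intensity sampled along one inward normal from the tissue edge.

    ``distance`` starts at 0 on the edge and increases strictly inward, in mm
    (or mm/sqrt(h) after distance normalization, tracked by ``scaled``).
    """

    distance: np.ndarray
    intensity: np.ndarray
    incubation_time: float | None = None
    condition: str = ""
    scaled: bool = False
    truncated: bool = False

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.distance.ndim != 1 or self.distance.shape != self.intensity.shape:
            raise ValueError("distance and intensity must be 1D and equally long")
        if len(self.distance) and (
            self.distance[0] != 0 or np.any(np.diff(self.distance) <= 0)
        ):
            raise ValueError("distance must start at 0 and increase strictly")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")


@dataclass
class ProfileEnsemble:
    """Mean of normalized profiles on a common scaled-distance grid with a
    pointwise 90% confidence band."""

    scaled_distance: np.ndarray
    mean_intensity: np.ndarray
    ci90_low: np.ndarray
    ci90_high: np.ndarray
    n_profiles: int
    condition: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scaled_distance": self.scaled_distance,
                "mean_intensity": self.mean_intensity,
                "ci90_low": self.ci90_low,
                "ci90_high": self.ci90_high,
            }
        )


@dataclass
class CellPoints:
    """Detected (or simulated) cell centroids in physical mm coordinates."""

    x: np.ndarray
    y: np.ndarray
    slice_id: str = "0"
    detection_params: dict[str, Any] = field(default_factory=dict)
    border_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have the same length")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) array of (x, y) in mm."""
        return np.column_stack([self.x, self.y])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"slice_id": self.slice_id, "x_mm": self.x, "y_mm": self.y})


@dataclass
class DensityGrid:
    """Area densities (cells/mm^2) on a downsampled grid.

    ``values[i, j]`` is the density at node (x, y) =
    (origin[0] + j * spacing, origin[1] + i * spacing). ``NaN`` marks nodes
    outside the tissue mask or not computable.
    """

    origin: tuple[float, float]
    spacing: float
    values: np.ndarray
    k: int = 8
    display_floor: float = 30.0
    display_ceiling: float = 1200.0
    edge_biased: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.k < 2:
            raise ValueError("k must be >= 2")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and np.any(finite < 0):
            raise ValueError("densities must be non-negative")

    @property
    def node_x(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.values.shape[1]) * self.spacing

    @property
    def node_y(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.values.shape[0]) * self.spacing


@dataclass
class PunctateMask:
    """Boolean map of pixels flagged as isolated high-intensity artifacts,
    together with the detection parameters that produced it."""

    flags: np.ndarray
    hp_size: int
    sd_window: int
    threshold_sd: float
    max_component_size: int = 2

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def count(self) -> int:
        return int(self.flags.sum())


@dataclass
class BiasField:
    """Smooth multiplicative intensity non-uniformity, normalized to mean 1."""

    values: np.ndarray
    order: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values <= 0):
            raise ValueError("bias field must be strictly positive")


@dataclass
class Sinogram:
    """Parallel-beam projections: detector position x view angle."""

    projections: np.ndarray
    angles: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=float)
        self.angles = np.asarray(self.angles, dtype=float)
        if self.projections.ndim != 2:
            raise ValueError("projections must be 2D (detector x angle)")
        if self.projections.shape[1] != len(self.angles):
            raise ValueError("number of projection columns must equal number of angles")
        if np.any(np.diff(self.angles) <= 0):
            raise ValueError("angles must be strictly increasing")

    @property
    def n_views(self) -> int:
        return len(self.angles)
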