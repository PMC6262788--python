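"""Core in-memory containers for stacks, movies, labels, ROIs and results.

Coordinate conventions
----------------------
Arrays are stored in numpy (plane, row, column) order: a 3D volume is indexed
``voxels[z, y, x]`` and a 2D xz slice ``pixels[z, x]``.  The API, however,
always speaks the anatomical convention of the analysis: x = anterior-posterior
(width), y = apical-basal (length), z = dorsal-ventral (depth), with spacings
given as ``(sx, sy, sz)`` in μm per voxel.  Physical positions refer to voxel
centers; voxel ``i`` along an axis with spacing ``s`` is centered at
``(i + 0.5) * s`` so that the half-open extent of the axis is ``[0, n * s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ImageStack3D",
    "TimeLapse2D",
    "CellLabelVolume",
    "RoiRect",
    "SliceImage2D",
    "CellMask2D",
    "ShapeMeasurement",
    "TissueAngleMeasurement",
    "IntensityRatioResult",
    "PolarityRatioResult",
    "BandQuantification",
    "CometSpot",
    "CometTrack",
    "CometSummary",
    "TestResult",
]


def _check_spacing(spacing, n: int) -> tuple:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != n:
        raise ValueError(f"expected {n} spacing values, got {len(spacing)}")
    if any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"all spacings must be positive and finite, got {spacing}")
    return spacing


@dataclass
class ImageStack3D:
    """A 3D scalar intensity grid with per-axis μm spacing.

    ``voxels`` is indexed ``[z, y, x]``; ``spacing`` is ``(sx, sy, sz)`` μm.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_name: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {self.voxels.ndim}")
        if any(d < 1 for d in self.voxels.shape):
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("stack intensities must be finite")
        self.spacing = _check_spacing(self.spacing, 3)

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical (x, y, z) extent in μm."""
        nz, ny, nx = self.voxels.shape
        sx, sy, sz = self.spacing
        return (nx * sx, ny * sy, nz * sz)


@dataclass
class TimeLapse2D:
    """An ordered single-plane time series with a fixed frame interval (s)."""

    frames: np.ndarray  # (t, y, x)
    pixel_spacing: tuple[float, float]  # (sx, sy) μm
    frame_interval: float  # seconds

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, y, x) array")
        self.pixel_spacing = _check_spacing(self.pixel_spacing, 2)
        self.frame_interval = float(self.frame_interval)
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass
class CellLabelVolume:
    """Integer cell labels aligned to a companion stack; 0 is background."""

    labels: np.ndarray  # (z, y, x) integer
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(f"expected 3 dimensions, got {self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self.spacing = _check_spacing(self.spacing, 3)

    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids != 0]

    def voxel_count(self, cell_id: int) -> int:
        return int(np.count_nonzero(self.labels == cell_id))


@dataclass(frozen=True)
class RoiRect:
    """Axis-aligned rectangle in μm, half-open: [origin, origin + size)."""

    origin: tuple[float, float]  # (x, y) μm
    width: float  # μm along x
    height: float  # μm along y

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0):
            raise ValueError("RoiRect width and height must be > 0")

    @property
    def x0(self) -> float:
        return self.origin[0]

    @property
    def y0(self) -> float:
        return self.origin[1]

    @property
    def x1(self) -> float:
        return self.origin[0] + self.width

    @property
    def y1(self) -> float:
        return self.origin[1] + self.height

    def overlaps(self, other: "RoiRect") -> bool:
        return (self.x0 < other.x1 and other.x0 < self.x1
                and self.y0 < other.y1 and other.y0 < self.y1)


@dataclass
class SliceImage2D:
    """A digital orthogonal xz slice taken at one apical-basal (y) position."""

    pixels: np.ndarray  # (z, x)
    spacing: tuple[float, float]  # (sx, sz) μm
    y_position: float  # μm

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2D")
        self.spacing = _check_spacing(self.spacing, 2)


@dataclass
class CellMask2D:
    """Binary mask of one cell within an xz slice."""

    mask: np.ndarray  # (z, x) bool
    spacing: tuple[float, float]  # (sx, sz) μm
    cell_id: int = 0

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2D")
        if not self.mask.any():
            raise ValueError("mask must be nonempty")
        self.spacing = _check_spacing(self.spacing, 2)


@dataclass
class ShapeMeasurement:
    """Per-cell, per-surface cross-section morphometry in the xz plane."""

    cell_id: int
    surface: str  # "apical" | "basal"
    area_um2: float
    depth_um: float
    depth_angle_deg: float
    width_um: float
    xz_ratio: float
    y_position_um: float
    anisotropic: bool


@dataclass
class TissueAngleMeasurement:
    """Interior angle of the basal tissue fold at its vertex."""

    vertex: tuple[float, float]  # (x, y) μm
    angle_deg: float


@dataclass
class IntensityRatioResult:
    """Region-normalized mean intensity: vertex ROI over flanking ROIs."""

    mhbc_mean: float
    midbrain_mean: float
    hindbrain_mean: float

    @property
    def normalized_mhbc(self) -> float:
        return self.mhbc_mean / ((self.midbrain_mean + self.hindbrain_mean) / 2.0)


@dataclass
class PolarityRatioResult:
    """Apical/middle and basal/middle mean-intensity ratios along the cell axis."""

    apical_mean: float
    middle_mean: float
    basal_mean: float

    @property
    def basal_ratio(self) -> float:
        return self.basal_mean / self.middle_mean

    @property
    def apical_ratio(self) -> float:
        return self.apical_mean / self.middle_mean


@dataclass
class BandQuantification:
    """Densitometry: target band over loading-control band, vs a control."""

    target_band: float
    loading_band: float
    normalized_level: float
    percent_of_control: float


@dataclass(frozen=True)
class CometSpot:
    frame: int
    position: tuple[float, float]  # (x, y) μm, sub-pixel
    quality: float = 0.0
    area_um2: Optional[float] = None


@dataclass
class CometTrack:
    spots: list[CometSpot] = field(default_factory=list)
    mean_speed: float = float("nan")  # μm/min

    def __post_init__(self):
        frames = [s.frame for s in self.spots]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("track frames must be strictly increasing")


@dataclass
class CometSummary:
    mean_speed: Optional[float]  # μm/min, None if no tracks
    comet_number: float  # mean detections per frame
    comet_size: float  # mean particle area μm²
    n_tracks: int
    n_frames: int


@dataclass
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    group_means: dict = field(default_factory=dict)
    group_sizes: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)
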