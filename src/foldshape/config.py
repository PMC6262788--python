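"""Pipeline configuration: every tunable of every stage, with validation.

Loaded from a flat YAML mapping; unknown keys are rejected so a typo in a
config file fails loudly rather than silently running defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    # --- slice geometry ---
    apical_slice_fraction: float = 1.0 / 6.0  # of cell length, from apical surface
    basal_slice_fraction: float = 5.0 / 6.0
    apical_is_min_y: bool = True  # apical surface at the low-y (midline) end
    slice_average_planes: int = 1  # y planes averaged per digital slice

    # --- shape metrics ---
    depth_max_angle_deg: float = 45.0  # depth chord must lie within this of z
    width_mode: str = "perpendicular"  # "perpendicular" | "x_axis"
    width_perp_tol_deg: float = 3.0  # angular gate for the perpendicular chord
    anisotropy_tolerance: float = 0.05  # |ratio - 1| beyond this flags anisotropy
    mhb_fit_span_um: float = 20.0  # basal-surface fit span per side

    # --- intensity metrics ---
    projection_extent_um: float = 10.0
    emtb_roi_um: tuple = (40.0, 50.0)  # (width, height) of region ROIs
    polarity_box_um2: float = 10.0  # area of the apical/middle/basal boxes
    polarity_fractions: tuple = (1.0 / 6.0, 0.5, 5.0 / 6.0)

    # --- comet tracking ---
    comet_crop_duration_s: float = 200.0
    comet_roi_um: tuple = (50.0, 40.0)
    blob_diameter_um: float = 1.0
    quality_threshold: float = 0.5
    auto_quality: bool = True  # Otsu auto-threshold on spot quality
    subpixel: bool = True
    max_link_radius_um: float = 1.5
    gap_frames: int = 2
    min_track_length: int = 5
    particle_min_area_um2: float = 0.05
    particle_max_area_um2: float = 5.0
    particle_presmooth_um: float = 0.3  # matched pre-filter before Otsu
    particle_split_touching: bool = True  # watershed-split abutting particles

    # --- statistics ---
    anova_gate_p: float = 0.05
    aggregate: str = "mean"  # per-embryo aggregation of replicate values

    # --- general ---
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not (0 < self.apical_slice_fraction < self.basal_slice_fraction < 1):
            raise ValueError("slice fractions must satisfy 0 < apical < basal < 1")
        if not (0 < self.depth_max_angle_deg <= 90):
            raise ValueError("depth_max_angle_deg must be in (0, 90]")
        if self.width_mode not in ("perpendicular", "x_axis"):
            raise ValueError(f"unknown width_mode {self.width_mode!r}")
        if self.width_perp_tol_deg <= 0:
            raise ValueError("width_perp_tol_deg must be > 0")
        if self.anisotropy_tolerance < 0:
            raise ValueError("anisotropy_tolerance must be >= 0")
        for name in ("mhb_fit_span_um", "projection_extent_um", "comet_crop_duration_s",
                     "blob_diameter_um", "max_link_radius_um", "polarity_box_um2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gap_frames < 0 or self.min_track_length < 2:
            raise ValueError("gap_frames >= 0 and min_track_length >= 2 required")
        if not (0 < self.particle_min_area_um2 < self.particle_max_area_um2):
            raise ValueError("particle area bounds must satisfy 0 < min < max")
        if self.particle_presmooth_um < 0:
            raise ValueError("particle_presmooth_um must be >= 0")
        if self.slice_average_planes < 1:
            raise ValueError("slice_average_planes must be >= 1")
        if not (0 < self.anova_gate_p <= 1):
            raise ValueError("anova_gate_p must be in (0, 1]")
        for tup, n in ((self.emtb_roi_um, 2), (self.comet_roi_um, 2),
                       (self.polarity_fractions, 3)):
            if len(tup) != n or any(v <= 0 for v in tup[:2]):
                raise ValueError("malformed tuple config value")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in ("emtb_roi_um", "comet_roi_um", "polarity_fractions"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file (empty file → all defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    return PipelineConfig.from_dict(data)
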