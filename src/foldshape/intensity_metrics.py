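"""ROI intensity normalizations.

Three normalizations, all ratios of mean intensities so that they are
invariant to the overall imaging gain: (i) the vertex-region (MHBC) mean
over the average of the two flanking-region means, measured on an average
intensity projection; (ii) apical/middle and basal/middle ratios along the
cell axis; (iii) densitometry of a target band over a loading-control band,
expressed as percent of a control condition.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (BandQuantification, ImageStack3D, IntensityRatioResult,
                    PolarityRatioResult, RoiRect)

log = logging.getLogger(__name__)

__all__ = [
    "average_projection",
    "roi_mean",
    "normalized_region_intensity",
    "polarity_ratios",
    "band_normalize",
    "polarity_boxes",
]


def average_projection(stack: ImageStack3D, z_extent: float = 10.0,
                       z_start: float = 0.0) -> np.ndarray:
    """Mean of ``round(z_extent/sz)`` consecutive planes starting at z_start.

    Returns a 2D (y, x) image.
    """
    sz = stack.spacing[2]
    nz = stack.voxels.shape[0]
    i0 = int(np.floor(z_start / sz))
    n = int(round(z_extent / sz))
    if n < 1:
        raise ValueError("z_extent smaller than one plane")
    if i0 < 0 or i0 + n > nz:
        raise ValueError(
            f"projection extent [{z_start}, {z_start + z_extent}) μm exceeds "
            f"the stack depth {nz * sz} μm")
    return stack.voxels[i0:i0 + n].mean(axis=0)


def roi_mean(image: np.ndarray, roi: RoiRect,
             pixel_spacing: tuple[float, float]) -> float:
    """Mean of the pixels whose centers fall in the half-open ROI."""
    sx, sy = pixel_spacing
    ny, nx = image.shape
    if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > nx * sx or roi.y1 > ny * sy:
        raise ValueError(f"ROI {roi} extends outside the image "
                         f"({nx * sx} × {ny * sy} μm)")
    # pixel i center (i + 0.5) s lies in [a, b)  ⇔  ceil(a/s - 0.5) ≤ i
    ix0 = int(np.ceil(roi.x0 / sx - 0.5))
    ix1 = int(np.ceil(roi.x1 / sx - 0.5))
    iy0 = int(np.ceil(roi.y0 / sy - 0.5))
    iy1 = int(np.ceil(roi.y1 / sy - 0.5))
    if ix1 <= ix0 or iy1 <= iy0:
        raise ValueError(f"ROI {roi} contains no pixel centers")
    return float(image[iy0:iy1, ix0:ix1].mean())


def normalized_region_intensity(image: np.ndarray, roi_mhbc: RoiRect,
                                roi_mid: RoiRect, roi_hind: RoiRect,
                                pixel_spacing: tuple[float, float]
                                ) -> IntensityRatioResult:
    """Vertex-region mean over the average of the two flanking means.

    Overlapping ROIs are tolerated with a logged warning (the measurement is
    still well defined); out-of-bounds ROIs raise.
    """
    rois = {"mhbc": roi_mhbc, "midbrain": roi_mid, "hindbrain": roi_hind}
    names = list(rois)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if rois[a].overlaps(rois[b]):
                log.warning("ROIs %s and %s overlap; computing anyway", a, b)
    means = {k: roi_mean(image, r, pixel_spacing) for k, r in rois.items()}
    return IntensityRatioResult(mhbc_mean=means["mhbc"],
                                midbrain_mean=means["midbrain"],
                                hindbrain_mean=means["hindbrain"])


def polarity_ratios(image: np.ndarray, box_apical: RoiRect,
                    box_middle: RoiRect, box_basal: RoiRect,
                    pixel_spacing: tuple[float, float]) -> PolarityRatioResult:
    """Apical/middle and basal/middle mean-intensity ratios."""
    apical = roi_mean(image, box_apical, pixel_spacing)
    middle = roi_mean(image, box_middle, pixel_spacing)
    basal = roi_mean(image, box_basal, pixel_spacing)
    if middle == 0:
        raise ValueError("middle-region mean is zero; ratios undefined")
    return PolarityRatioResult(apical_mean=apical, middle_mean=middle,
                               basal_mean=basal)


def polarity_boxes(cell_axis_x: float, cell_top_y: float, cell_length: float,
                   box_area_um2: float = 10.0,
                   fractions: tuple = (1 / 6, 0.5, 5 / 6)):
    """Square boxes of the given area centered on the cell axis at the given
    fractions of the cell length (apical, middle, basal).

    The box is interpreted as a square whose *area* is ``box_area_um2``
    (side ≈ 3.16 μm for 10 μm²).
    """
    side = float(np.sqrt(box_area_um2))
    boxes = []
    for frac in fractions:
        cy = cell_top_y + frac * cell_length
        boxes.append(RoiRect(origin=(cell_axis_x - side / 2, cy - side / 2),
                             width=side, height=side))
    return tuple(boxes)


def band_normalize(target_band: float, loading_band: float,
                   control_value: float = 1.0) -> BandQuantification:
    """Densitometry: target over loading control, as percent of a control."""
    if loading_band <= 0:
        raise ValueError("loading band must be > 0")
    if control_value <= 0:
        raise ValueError("control value must be > 0")
    level = target_band / loading_band
    return BandQuantification(target_band=target_band,
                              loading_band=loading_band,
                              normalized_level=level,
                              percent_of_control=100.0 * level / control_value)
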