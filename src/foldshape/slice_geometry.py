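"""Stack alignment and digital orthogonal (xz) slice extraction.

The measurement protocol first rotates the stack in the xy plane so that the
apical-basal axis of the cell of interest runs parallel to y, measures the
cell's length along y, divides the length into six equal sections, and takes
one single-voxel xz slice at the section point just inside each surface
(1/6 from the apical end, 5/6 from the apical end — about 5-7 μm into a
30-42 μm cell).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .types import CellLabelVolume, CellMask2D, ImageStack3D, SliceImage2D

__all__ = [
    "rotate_stack_xy",
    "estimate_alignment_angle",
    "cell_length_y",
    "slice_positions",
    "extract_xz_slice",
    "extract_cell_masks",
]


def rotate_stack_xy(volume, angle_deg: float):
    """Rotate every xy plane about its center by ``angle_deg``; z untouched.

    Positive angles rotate image content from the +y axis toward the +x axis.
    Intensity stacks are interpolated bilinearly, label volumes
    nearest-neighbor.  Returns a new object of the same type.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("rotation angle must be finite")
    if isinstance(volume, ImageStack3D):
        sx, sy, _ = volume.spacing
        _check_isotropic_xy(sx, sy)
        rotated = ndimage.rotate(volume.voxels.astype(float), angle_deg,
                                 axes=(1, 2), reshape=False, order=1,
                                 mode="constant", cval=0.0)
        return ImageStack3D(voxels=rotated, spacing=volume.spacing,
                            channel_name=volume.channel_name)
    if isinstance(volume, CellLabelVolume):
        sx, sy, _ = volume.spacing
        _check_isotropic_xy(sx, sy)
        rotated = ndimage.rotate(volume.labels, angle_deg, axes=(1, 2),
                                 reshape=False, order=0, mode="constant",
                                 cval=0)
        return CellLabelVolume(labels=rotated, spacing=volume.spacing)
    raise TypeError(f"cannot rotate object of type {type(volume).__name__}")


def _check_isotropic_xy(sx: float, sy: float) -> None:
    if abs(sx - sy) > 1e-9 * max(sx, sy):
        raise ValueError(
            f"xy rotation requires isotropic xy spacing, got sx={sx}, sy={sy}")


def estimate_alignment_angle(labels: CellLabelVolume, cell_id: int,
                             min_axis_ratio: float = 1.1) -> float:
    """Angle (degrees) to pass to :func:`rotate_stack_xy` so the cell's
    principal xy axis becomes parallel to y.

    Computed from the second central moments of the cell's xy projection.
    Raises if the projection has no principal axis (near-isotropic cell).
    """
    mask = labels.labels == cell_id
    if not mask.any():
        raise ValueError(f"no cell with label {cell_id}")
    proj = mask.any(axis=0)  # (y, x)
    yy, xx = np.nonzero(proj)
    pts = np.stack([yy.astype(float), xx.astype(float)])
    cov = np.cov(pts)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or evals[1] / max(evals[0], 1e-12) < min_axis_ratio:
        raise ValueError(
            f"cell {cell_id} xy projection is isotropic; no principal axis")
    vy, vx = evecs[:, 1]  # major axis, components (y, x)
    if vy < 0:
        vy, vx = -vy, -vx
    # rotating content by `a` maps direction (y,x) -> (y cos a - x sin a,
    # y sin a + x cos a); choose a so the rotated x-component vanishes.
    angle = -np.degrees(np.arctan2(vx, vy))
    if angle > 90:
        angle -= 180
    elif angle <= -90:
        angle += 180
    return float(angle)


def cell_length_y(labels: CellLabelVolume, cell_id: int) -> float:
    """Apical-basal (y) extent of the cell in μm: (max y − min y + 1) × sy."""
    mask = labels.labels == cell_id
    if not mask.any():
        raise ValueError(f"no cell with label {cell_id}")
    ys = np.nonzero(mask.any(axis=(0, 2)))[0]
    sy = labels.spacing[1]
    return float((ys.max() - ys.min() + 1) * sy)


def slice_positions(cell_length: float) -> tuple[float, float]:
    """Apical and basal slice offsets from the apical surface, in μm.

    The cell length is divided into six equal sections; the apical slice sits
    at the first section point (length/6) and the basal slice at the last
    (5·length/6).
    """
    if not cell_length > 0:
        raise ValueError(f"cell length must be > 0, got {cell_length}")
    return (cell_length / 6.0, 5.0 * cell_length / 6.0)


def _y_index(volume, y_um: float) -> int:
    sy = volume.spacing[1]
    ny = (volume.voxels if isinstance(volume, ImageStack3D)
          else volume.labels).shape[1]
    if not (0 <= y_um < ny * sy):
        raise ValueError(f"y = {y_um} μm outside stack extent [0, {ny * sy})")
    return int(np.floor(y_um / sy))


def extract_xz_slice(volume, y_um: float, n_average: int = 1) -> SliceImage2D:
    """The xz plane at the voxel row containing ``y_um``.

    ``n_average`` > 1 averages that many consecutive y planes centered on the
    target row (clipped at the stack edges) — useful for noisy data; the
    default single-plane slice matches the digital orthogonal cross-section.
    """
    if isinstance(volume, CellLabelVolume):
        raise TypeError("use extract_cell_masks for label volumes")
    iy = _y_index(volume, y_um)
    sx, sy, sz = volume.spacing
    ny = volume.voxels.shape[1]
    if n_average <= 1:
        plane = volume.voxels[:, iy, :]
    else:
        lo = max(0, iy - (n_average - 1) // 2)
        hi = min(ny, lo + n_average)
        plane = volume.voxels[:, lo:hi, :].mean(axis=1)
    return SliceImage2D(pixels=np.array(plane), spacing=(sx, sz),
                        y_position=y_um)


def extract_cell_masks(labels: CellLabelVolume, y_um: float) -> dict[int, CellMask2D]:
    """One CellMask2D per label present in the xz plane at ``y_um``.

    Labels absent from that plane are simply omitted.
    """
    iy = _y_index(labels, y_um)
    sx, sy, sz = labels.spacing
    plane = labels.labels[:, iy, :]
    out = {}
    for cid in np.unique(plane):
        if cid == 0:
            continue
        out[int(cid)] = CellMask2D(mask=plane == cid, spacing=(sx, sz),
                                   cell_id=int(cid))
    return out
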