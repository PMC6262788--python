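"""Anisotropy morphometry on xz cell masks.

Three measurements per cross-section, mirroring the manual line-tool
protocol: (i) cell area; (ii) maximal depth — the longest in-mask chord whose
direction lies within 45° (inclusive) of the z-axis; (iii) maximal width —
the longest in-mask chord perpendicular to the realized depth chord.  The
x:z ratio is width divided by depth; a ratio different from 1 (beyond a
small tolerance) flags anisotropic, i.e. polarized, cell shape.

Chord conventions
-----------------
Candidate chord endpoints are boundary pixels; a chord is "in-mask" when the
supercover rasterization of the segment between the endpoint pixel centers
lies entirely in the mask.  Chord length is the Euclidean distance between
the endpoint centers *plus the extent of one pixel along the chord
direction* (``|ux|·sx + |uz|·sz``), so that a one-pixel-wide bar of n pixels
measures n·s and a square of side s measures s√2 along its diagonal — the
lengths a line tool reports on the continuous pixel-square geometry.
Ties are broken toward the smaller chord angle, then lexicographically
smaller endpoints.  Angles are computed in physical (μm) coordinates, so
anisotropic pixel spacing is handled correctly.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .rasterize import boundary_pixels, segment_inside
from .types import (CellLabelVolume, CellMask2D, ImageStack3D,
                    ShapeMeasurement, TissueAngleMeasurement)

__all__ = [
    "mask_area",
    "max_depth_chord",
    "max_width_perpendicular",
    "xz_ratio",
    "is_anisotropic",
    "measure_cell_shape",
    "measure_all_cells",
    "measure_mhb_angle",
]


def mask_area(mask: CellMask2D) -> float:
    """Cross-section area in μm²: pixel count × sx × sz."""
    sx, sz = mask.spacing
    return float(np.count_nonzero(mask.mask) * sx * sz)


def _chord_candidates(mask: CellMask2D):
    """All ordered boundary-pixel pairs with their physical geometry.

    Returns (pairs, dx_um, dz_um, length_um, angle_from_z_deg) where pairs is
    (n, 4) of (z0, x0, z1, x1) with (z0, x0) <= (z1, x1) lexicographically.
    """
    sx, sz = mask.spacing
    bp = boundary_pixels(mask.mask)  # (m, 2) of (z, x), lex sorted
    m = len(bp)
    if m < 2:
        return (np.empty((0, 4), dtype=int), np.empty(0), np.empty(0),
                np.empty(0), np.empty(0))
    i, j = np.triu_indices(m, k=1)
    p0 = bp[i]
    p1 = bp[j]
    dz = (p1[:, 0] - p0[:, 0]) * sz
    dx = (p1[:, 1] - p0[:, 1]) * sx
    dist = np.hypot(dx, dz)
    ux = np.abs(dx) / dist
    uz = np.abs(dz) / dist
    length = dist + ux * sx + uz * sz
    angle = np.degrees(np.arctan2(np.abs(dx), np.abs(dz)))
    pairs = np.concatenate([p0, p1], axis=1)
    return pairs, dx, dz, length, angle


def _best_chord(mask: CellMask2D, keep: np.ndarray, pairs, length, tiebreak):
    """Longest in-mask chord among ``keep`` candidates.

    ``tiebreak`` is an array sorted ascending on ties (e.g. chord angle).
    Candidates are visited in order (length desc, tiebreak asc, endpoints
    lex asc); the first whose supercover lies inside the mask wins — which
    equals the exhaustive maximum because insideness does not depend on rank.
    """
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        return None
    sub_pairs = pairs[idx]
    order = np.lexsort((sub_pairs[:, 3], sub_pairs[:, 2], sub_pairs[:, 1],
                        sub_pairs[:, 0], tiebreak[idx], -length[idx]))
    for k in order:
        z0, x0, z1, x1 = sub_pairs[k]
        if segment_inside(mask.mask, z0, x0, z1, x1):
            return idx[k]
    return None


def max_depth_chord(mask: CellMask2D, max_angle: float = 45.0):
    """Deepest in-mask chord within ``max_angle`` (inclusive) of the z-axis.

    Returns ``(depth_um, angle_deg)``.  A single-pixel mask degenerates to
    the pixel's z extent at angle 0.
    """
    sx, sz = mask.spacing
    pairs, dx, dz, length, angle = _chord_candidates(mask)
    keep = angle <= max_angle + 1e-9
    best = _best_chord(mask, keep, pairs, length, angle)
    if best is None:
        # degenerate: single pixel (or no admissible pair) → z extent
        return float(sz), 0.0
    return float(length[best]), float(angle[best])


def max_width_perpendicular(mask: CellMask2D, depth_angle: float,
                            width_mode: str = "perpendicular",
                            perp_tol: float = 3.0):
    """Widest in-mask chord perpendicular to the depth chord, in μm.

    The perpendicular direction cannot in general be realized exactly by
    pixel-center pairs, so candidates are gated to directions within
    ``perp_tol`` degrees of the perpendicular; ties break toward the smaller
    angular deviation.  ``width_mode="x_axis"`` measures along the raw x-axis
    instead (the two coincide when the depth chord is z-aligned).
    """
    sx, sz = mask.spacing
    if width_mode == "x_axis":
        target = 90.0  # from z-axis
    elif width_mode == "perpendicular":
        target = 90.0 - depth_angle
    else:
        raise ValueError(f"unknown width_mode {width_mode!r}")
    pairs, dx, dz, length, angle = _chord_candidates(mask)
    deviation = np.abs(angle - target)
    keep = deviation <= perp_tol + 1e-9
    best = _best_chord(mask, keep, pairs, length, deviation)
    if best is None:
        # fall back to the extent of one pixel along the target direction
        t = np.radians(target)
        return float(abs(np.sin(t)) * sx + abs(np.cos(t)) * sz)
    return float(length[best])


def xz_ratio(width_x: float, depth_z: float) -> float:
    """Anisotropy ratio: width (x) divided by depth (z)."""
    if not depth_z > 0:
        raise ValueError(f"depth must be > 0, got {depth_z}")
    return width_x / depth_z


def is_anisotropic(ratio: float, tolerance: float = 0.05) -> bool:
    """Shape is anisotropic when the x:z ratio differs from 1 beyond tolerance."""
    return abs(ratio - 1.0) > tolerance


def measure_cell_shape(stack, labels: CellLabelVolume, cell_id: int,
                       surface: str,
                       config: PipelineConfig | None = None) -> ShapeMeasurement:
    """Full per-cell, per-surface measurement.

    Aligns the cell's apical-basal axis to y (cropping to the cell's
    neighbourhood first), measures the cell length, takes the digital xz
    slice at the 1/6 (apical) or 5/6 (basal) section point, and computes
    area, depth, width and the x:z ratio on the cell's mask in that slice.
    """
    from .slice_geometry import (cell_length_y, estimate_alignment_angle,
                                 extract_cell_masks, rotate_stack_xy,
                                 slice_positions)

    config = config or PipelineConfig()
    if surface not in ("apical", "basal"):
        raise ValueError(f"surface must be 'apical' or 'basal', got {surface!r}")
    crop = _crop_to_cell(labels, cell_id)
    try:
        angle = estimate_alignment_angle(crop, cell_id)
    except ValueError:
        angle = 0.0  # already-isotropic projection: nothing to align
    aligned = rotate_stack_xy(crop, angle) if angle != 0.0 else crop
    length = cell_length_y(aligned, cell_id)
    y_apical, y_basal = slice_positions(length)
    if not config.apical_is_min_y:
        y_apical, y_basal = y_basal, y_apical
    offset = y_apical if surface == "apical" else y_basal
    mask_y = _cell_min_y_um(aligned, cell_id) + offset
    masks = extract_cell_masks(aligned, mask_y)
    if cell_id not in masks:
        raise ValueError(
            f"extract_xz_slice: cell {cell_id} absent at the {surface} slice "
            f"(y = {mask_y:.2f} μm)")
    mask = masks[cell_id]
    area = mask_area(mask)
    depth, depth_angle = max_depth_chord(mask, config.depth_max_angle_deg)
    width = max_width_perpendicular(mask, depth_angle,
                                    width_mode=config.width_mode,
                                    perp_tol=config.width_perp_tol_deg)
    ratio = xz_ratio(width, depth)
    return ShapeMeasurement(
        cell_id=cell_id, surface=surface, area_um2=area, depth_um=depth,
        depth_angle_deg=depth_angle, width_um=width, xz_ratio=ratio,
        y_position_um=offset,
        anisotropic=is_anisotropic(ratio, config.anisotropy_tolerance))


def measure_all_cells(stack, labels: CellLabelVolume,
                      config: PipelineConfig | None = None,
                      cell_ids=None, surfaces=("apical", "basal")):
    """measure_cell_shape over every cell and surface; returns a list."""
    out = []
    for cid in (cell_ids if cell_ids is not None else labels.cell_ids()):
        for surface in surfaces:
            out.append(measure_cell_shape(stack, labels, int(cid), surface,
                                          config))
    return out


def _crop_to_cell(labels: CellLabelVolume, cell_id: int,
                  pad_um: float = 2.0) -> CellLabelVolume:
    """Crop the label volume to the cell's bounding box, padded enough that
    an in-plane rotation of the cell stays inside the crop."""
    mask = labels.labels == cell_id
    if not mask.any():
        raise ValueError(f"no cell with label {cell_id}")
    zz, yy, xx = np.nonzero(mask)
    sx, sy, sz = labels.spacing
    # pad xy to the half-diagonal so any rotation keeps the cell in frame
    ey = (yy.max() - yy.min() + 1)
    ex = (xx.max() - xx.min() + 1)
    half_diag = int(np.ceil(0.5 * np.hypot(ex, ey)))
    py = half_diag - ey // 2 + int(np.ceil(pad_um / sy))
    px = half_diag - ex // 2 + int(np.ceil(pad_um / sx))
    ny, nx = labels.labels.shape[1:]
    y0, y1 = max(0, yy.min() - py), min(ny, yy.max() + 1 + py)
    x0, x1 = max(0, xx.min() - px), min(nx, xx.max() + 1 + px)
    sub = labels.labels[:, y0:y1, x0:x1].copy()
    sub[sub != cell_id] = 0
    return CellLabelVolume(labels=sub, spacing=labels.spacing)


def _cell_min_y_um(labels: CellLabelVolume, cell_id: int) -> float:
    ys = np.nonzero((labels.labels == cell_id).any(axis=(0, 2)))[0]
    return float(ys.min() * labels.spacing[1])


def measure_mhb_angle(points, vertex_index: int,
                      fit_span: float = 20.0) -> TissueAngleMeasurement:
    """Interior tissue angle at the basal fold vertex.

    ``points`` is an ordered (n, 2) array of (x, y) μm along the basal
    surface; ``vertex_index`` marks the vertex.  A total-least-squares line
    is fitted to the points within ``fit_span`` μm of the vertex on each
    side; the angle between the two fitted directions, each oriented away
    from the vertex, is returned in (0°, 180°].
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (x, y) μm")
    if not (0 <= vertex_index < len(pts)):
        raise ValueError("vertex_index out of range")
    vertex = pts[vertex_index]
    dist = np.linalg.norm(pts - vertex, axis=1)
    directions = []
    for side in ("left", "right"):
        if side == "left":
            sel = (np.arange(len(pts)) < vertex_index) & (dist <= fit_span)
        else:
            sel = (np.arange(len(pts)) > vertex_index) & (dist <= fit_span)
        side_pts = pts[sel]
        if len(side_pts) < 3:
            raise ValueError(
                f"need >= 3 points within {fit_span} μm of the vertex on the "
                f"{side} side, got {len(side_pts)}")
        centered = np.concatenate([side_pts, [vertex]]) - vertex
        # TLS direction = principal eigenvector of the scatter about the vertex
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        d = vt[0]
        if d @ (side_pts.mean(axis=0) - vertex) < 0:
            d = -d
        directions.append(d)
    cosang = float(np.clip(directions[0] @ directions[1], -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    if angle < 1e-6:
        raise ValueError("degenerate surface: both sides run in the same direction")
    return TissueAngleMeasurement(vertex=(float(vertex[0]), float(vertex[1])),
                                  angle_deg=angle)
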