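"""Ground-truth-annotated synthetic inputs for every pipeline stage.

Three generators:

* :func:`generate_epithelium_stack` — a single-layer pseudostratified
  epithelium folded basally at a vertex: two flat sheets of columnar cells
  tilted toward each other so their basal anchors lie on a V whose interior
  angle is ``fold_angle``, plus one vertical cell whose basal end sits at the
  vertex itself (the constriction-point cell).  Each cell is a prism along
  its own apical-basal axis with an elliptical cross-section in the plane
  perpendicular to that axis: depth (z) is constant and width interpolates
  linearly so that it equals ``apical_xz_ratio × depth`` at the apical
  measurement plane (1/6 of the length) and ``basal_xz_ratio × depth`` at
  the basal plane (5/6) — the planes where the analysis takes its digital
  slices, which makes the recorded ground truth exact at those planes.
  Near a sharp fold, straight prisms of fixed width cannot tile the corner
  without crossing the midline, so sheet cells keep a geometric stand-off
  from the vertex; real vertex cells taper and bend, which this generator
  deliberately does not model.  The membrane channel is the label-boundary
  shell (given a thickness), blurred by a Gaussian PSF, peak-normalized to
  100 intensity units, plus additive Gaussian noise — so SNR = 100/noise_sd.

* :func:`generate_comet_movie` — point-like particles (2D Gaussian blobs,
  peak 100) moving ballistically with per-comet speeds drawn from
  N(speed, speed_sd²); comets leaving the field are replaced by fresh ones
  so the expected in-field count stays constant.

* :func:`generate_region_intensity_stack` — a piecewise-constant stack with
  stated mean intensities inside three rectangular regions.

All generators are deterministic for a fixed seed; each draws from its own
named substream of the global seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import find_boundaries

from .types import CellLabelVolume, ImageStack3D, RoiRect, TimeLapse2D

__all__ = [
    "EpitheliumParams",
    "CometMovieParams",
    "generate_epithelium_stack",
    "generate_comet_movie",
    "generate_region_intensity_stack",
    "observable_track_speeds",
]

_MEMBRANE_PEAK = 100.0
_COMET_PEAK = 100.0


@dataclass
class EpitheliumParams:
    n_cells_per_side: int = 3
    cell_length: float = 36.0           # μm, apical-basal
    apical_xz_ratio: float = 0.7        # width/depth at the apical slice plane
    basal_xz_ratio: float = 0.5         # width/depth at the basal slice plane
    cell_depth_z: float = 12.0          # μm, z extent of the cross-section
    fold_angle: float = 90.0            # degrees, interior basal angle
    midline_y: float | None = None      # μm, y of the basal vertex (auto if None)
    membrane_thickness: float = 0.4     # μm
    psf_sigma: float = 0.3              # μm
    noise_sd: float = 10.0              # intensity units (peak signal = 100)
    spacing: tuple = (0.2, 0.2, 0.5)    # (sx, sy, sz) μm/voxel
    seed: int = 0
    include_vertex_cell: bool = True
    cell_gap: float = 0.6               # μm between neighboring cells

    def __post_init__(self):
        if self.apical_xz_ratio <= 0 or self.basal_xz_ratio <= 0:
            raise ValueError("xz ratios must be > 0")
        if not (0 < self.fold_angle <= 180):
            raise ValueError("fold_angle must be in (0, 180] degrees")
        if self.cell_length <= 0 or self.cell_depth_z <= 0:
            raise ValueError("cell dimensions must be > 0")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be > 0")
        if self.n_cells_per_side < 0:
            raise ValueError("n_cells_per_side must be >= 0")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sd and psf_sigma must be >= 0")

    def width_at(self, u: float) -> float:
        """Cross-section width (μm) at axial position u ∈ [0, L] from apical."""
        L = self.cell_length
        frac = (u / L - 1.0 / 6.0) / (2.0 / 3.0)
        ratio = self.apical_xz_ratio + (self.basal_xz_ratio
                                        - self.apical_xz_ratio) * frac
        return ratio * self.cell_depth_z


def _cell_axes(p: EpitheliumParams):
    """Cell descriptors: (id, apical point (x,y) μm, unit axis (x,y), side).

    y increases basally (downward into the fold); the basal vertex is at
    (0, 0) in this intermediate frame, apical ends at negative y.
    """
    eps = np.radians(90.0 - p.fold_angle / 2.0)  # ray elevation
    L = p.cell_length
    w_max = max(p.width_at(0.0), p.width_at(L))
    pitch = w_max + p.cell_gap
    x_clear = (w_max / 2.0 + p.cell_gap) if p.include_vertex_cell else p.cell_gap
    v_first = (x_clear + L * np.sin(eps)) / np.cos(eps) + w_max / 2.0
    cells = []
    cid = 1
    if p.include_vertex_cell:
        cells.append(dict(cell_id=cid, apical=np.array([0.0, -L]),
                          axis=np.array([0.0, 1.0]), side="vertex"))
        cid += 1
    for sgn, side in ((1.0, "right"), (-1.0, "left")):
        ray = np.array([sgn * np.cos(eps), -np.sin(eps)])
        axis = np.array([sgn * np.sin(eps), np.cos(eps)])
        for k in range(p.n_cells_per_side):
            v = v_first + k * pitch
            basal = v * ray
            cells.append(dict(cell_id=cid, apical=basal - L * axis,
                              axis=axis, side=side))
            cid += 1
    return cells, pitch, w_max


def generate_epithelium_stack(params: EpitheliumParams):
    """Build (membrane ImageStack3D, CellLabelVolume, ground-truth dict).

    The ground-truth dict has two DataFrames: ``"cells"`` with one row per
    cell (true widths/depth/ratios/length and geometry) and
    ``"basal_surface"`` with the basal V polyline quantized to voxel centers
    (columns x_um, y_um, plus the vertex index in ``attrs``).
    """
    p = params
    sx, sy, sz = p.spacing
    L, d = p.cell_length, p.cell_depth_z
    cells, pitch, w_max = _cell_axes(p)

    # --- bounds of the tissue in the intermediate frame (vertex at origin)
    pad = 2.0 + 3.0 * p.psf_sigma
    xs, ys = [], []
    for c in cells:
        for u in (0.0, L):
            centre = c["apical"] + u * c["axis"]
            xs += [centre[0] - w_max, centre[0] + w_max]
            ys += [centre[1] - w_max, centre[1] + w_max]
    x_lo, x_hi = min(xs) - pad, max(xs) + pad
    y_lo, y_hi = min(ys) - pad, max(ys) + pad
    y_hi = max(y_hi, pad)  # include the vertex itself
    if p.midline_y is not None:
        # place the basal vertex at y = midline_y in the output frame
        if -p.midline_y > y_lo:
            raise ValueError(
                f"midline_y={p.midline_y} leaves no room for the cells "
                f"(need at least {-y_lo:.1f} μm above the vertex)")
        y_lo = -p.midline_y
    nz = int(np.ceil((d + 2 * pad) / sz))
    ny = int(np.ceil((y_hi - y_lo) / sy))
    nx = int(np.ceil((x_hi - x_lo) / sx))

    # voxel-center coordinates in the intermediate frame
    xc = x_lo + (np.arange(nx) + 0.5) * sx
    yc = y_lo + (np.arange(ny) + 0.5) * sy
    zc = (np.arange(nz) + 0.5) * sz
    z_mid = nz * sz / 2.0
    X, Y = np.meshgrid(xc, yc)          # (ny, nx)
    z_term = ((zc - z_mid) / (d / 2.0)) ** 2  # (nz,)

    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    truth_rows = []
    for c in cells:
        ax, ay = c["axis"]
        apx, apy = c["apical"]
        U = (X - apx) * ax + (Y - apy) * ay          # axial coordinate
        V = (X - apx) * (-ay) + (Y - apy) * ax       # transverse coordinate
        in_span = (U >= 0) & (U < L)
        Ucl = np.clip(U, 0.0, L)
        halfw = np.maximum(_width_profile(p, Ucl) / 2.0, 1e-9)
        v_term = (V / halfw) ** 2                    # (ny, nx)
        inside = in_span[None] & (v_term[None] + z_term[:, None, None] <= 1.0)
        clash = inside & (labels != 0)
        if clash.any():
            raise ValueError(
                f"cell {c['cell_id']} overlaps an existing cell; reduce "
                f"n_cells_per_side/cell widths or increase fold_angle")
        labels[inside] = c["cell_id"]
        if not inside.any():
            raise ValueError(
                f"cell {c['cell_id']} lies outside the volume; check "
                f"fold_angle/cell_length/spacing")
        truth_rows.append(dict(
            cell_id=c["cell_id"], side=c["side"],
            length_um=L, depth_um=d,
            apical_width_um=p.apical_xz_ratio * d,
            basal_width_um=p.basal_xz_ratio * d,
            apical_ratio=(p.apical_xz_ratio * d) / d,
            basal_ratio=(p.basal_xz_ratio * d) / d,
            axis_angle_deg=float(np.degrees(np.arctan2(ax, ay))),
            basal_x_um=apx + L * ax - x_lo, basal_y_um=apy + L * ay - y_lo))

    # --- membrane channel: boundary shell -> thickness -> PSF -> noise
    shell = find_boundaries(labels, mode="inner", connectivity=1)
    if p.membrane_thickness / 2.0 > min(p.spacing):
        dist = ndimage.distance_transform_edt(~shell, sampling=(sz, sy, sx))
        shell = dist <= p.membrane_thickness / 2.0
    membrane = shell.astype(np.float32)
    if p.psf_sigma > 0:
        membrane = ndimage.gaussian_filter(
            membrane, sigma=(p.psf_sigma / sz, p.psf_sigma / sy,
                             p.psf_sigma / sx))
    peak = membrane.max()
    if peak > 0:
        membrane *= _MEMBRANE_PEAK / peak
    if p.noise_sd > 0:
        rng = np.random.default_rng([p.seed, 1])
        membrane = membrane + rng.normal(0.0, p.noise_sd,
                                         membrane.shape).astype(np.float32)

    # --- basal surface polyline (quantized to voxel centers)
    eps = np.radians(90.0 - p.fold_angle / 2.0)
    x_surf = np.arange(x_lo + pad, x_hi - pad, sx)
    y_surf = -np.abs(x_surf) * np.tan(eps)
    y_q = (np.floor((y_surf - y_lo) / sy) + 0.5) * sy
    x_q = x_surf - x_lo
    surface = pd.DataFrame({"x_um": x_q, "y_um": y_q})
    surface.attrs["vertex_index"] = int(np.argmin(np.abs(x_surf)))

    truth = {"cells": pd.DataFrame(truth_rows), "basal_surface": surface}
    stack = ImageStack3D(voxels=membrane.astype(np.float32),
                         spacing=p.spacing, channel_name="membrane")
    label_volume = CellLabelVolume(labels=labels, spacing=p.spacing)
    return stack, label_volume, truth


def _width_profile(p: EpitheliumParams, u):
    frac = (np.asarray(u) / p.cell_length - 1.0 / 6.0) / (2.0 / 3.0)
    ratio = p.apical_xz_ratio + (p.basal_xz_ratio - p.apical_xz_ratio) * frac
    return ratio * p.cell_depth_z


# ---------------------------------------------------------------------------
# Comet movies


@dataclass
class CometMovieParams:
    n_comets: int = 30
    speed: float = 4.5                  # μm/min
    speed_sd: float = 0.5               # μm/min
    comet_sigma: float = 0.35           # μm, Gaussian blob sd
    direction_model: str = "isotropic"  # "isotropic" | "apical-basal-biased"
    duration: float = 600.0             # s
    frame_interval: float = 4.0         # s
    snr: float = 10.0                   # blob peak / noise sd
    spacing: tuple = (0.2, 0.2)         # (sx, sy) μm/pixel
    field_size_um: tuple = (60.0, 50.0)  # (x, y) extent
    seed: int = 0

    def __post_init__(self):
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.duration < self.frame_interval:
            raise ValueError("duration must be >= frame_interval")
        if self.n_comets < 0:
            raise ValueError("n_comets must be >= 0")
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.direction_model not in ("isotropic", "apical-basal-biased"):
            raise ValueError(f"unknown direction_model {self.direction_model!r}")


def _new_comet(p: CometMovieParams, rng, track_id: int):
    wx, wy = p.field_size_um
    pos = rng.uniform([0, 0], [wx, wy])
    speed = max(0.0, rng.normal(p.speed, p.speed_sd)) if p.speed_sd > 0 \
        else p.speed
    if p.direction_model == "isotropic":
        theta = rng.uniform(0, 2 * np.pi)
    else:
        # predominantly along y (the apical-basal direction), either way
        theta = np.pi / 2 + rng.normal(0, np.pi / 12)
        if rng.random() < 0.5:
            theta += np.pi
    vel = speed / 60.0 * np.array([np.cos(theta), np.sin(theta)])  # μm/s
    return dict(track_id=track_id, pos=pos, vel=vel, speed=speed)


def generate_comet_movie(params: CometMovieParams):
    """Build (TimeLapse2D, ground-truth dict).

    The ground-truth dict holds ``"positions"`` (track_id, frame, x_um, y_um)
    and ``"tracks"`` (track_id, speed_um_min) DataFrames.  Comets move
    ballistically; a comet whose center leaves the field is replaced by a
    fresh one so the in-field count stays at ``n_comets`` every frame.
    """
    p = params
    rng = np.random.default_rng([p.seed, 2])
    sx, sy = p.spacing
    wx, wy = p.field_size_um
    nx, ny = int(round(wx / sx)), int(round(wy / sy))
    n_frames = int(np.floor(p.duration / p.frame_interval))
    comets = []
    next_id = 0
    for _ in range(p.n_comets):
        comets.append(_new_comet(p, rng, next_id))
        next_id += 1
    pos_rows = []
    track_speed = {c["track_id"]: c["speed"] for c in comets}

    frames = np.zeros((n_frames, ny, nx), dtype=np.float32)
    sig_px = p.comet_sigma / sx
    for f in range(n_frames):
        for c in comets:
            x, y = c["pos"]
            pos_rows.append(dict(track_id=c["track_id"], frame=f,
                                 x_um=x, y_um=y))
            _render_blob(frames[f], x / sx, y / sy, sig_px, _COMET_PEAK)
        # advance and replace leavers
        survivors = []
        for c in comets:
            c["pos"] = c["pos"] + c["vel"] * p.frame_interval
            if 0 <= c["pos"][0] < wx and 0 <= c["pos"][1] < wy:
                survivors.append(c)
        while len(survivors) < p.n_comets:
            nc = _new_comet(p, rng, next_id)
            next_id += 1
            track_speed[nc["track_id"]] = nc["speed"]
            survivors.append(nc)
        comets = survivors
    if p.snr > 0 and p.n_comets >= 0:
        noise_sd = _COMET_PEAK / p.snr
        frames += rng.normal(0.0, noise_sd, frames.shape).astype(np.float32)

    positions = pd.DataFrame(pos_rows,
                             columns=["track_id", "frame", "x_um", "y_um"])
    seen = positions["track_id"].unique() if len(pos_rows) else []
    tracks = pd.DataFrame(
        [{"track_id": t, "speed_um_min": track_speed[t]} for t in seen],
        columns=["track_id", "speed_um_min"])
    movie = TimeLapse2D(frames=frames, pixel_spacing=p.spacing,
                        frame_interval=p.frame_interval)
    return movie, {"positions": positions, "tracks": tracks}


def _render_blob(frame: np.ndarray, cx_px: float, cy_px: float,
                 sigma_px: float, peak: float) -> None:
    """Add a Gaussian blob in-place; only a ±4σ window is touched."""
    ny, nx = frame.shape
    r = int(np.ceil(4 * sigma_px)) + 1
    x0, x1 = max(0, int(cx_px) - r), min(nx, int(cx_px) + r + 1)
    y0, y1 = max(0, int(cy_px) - r), min(ny, int(cy_px) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) + 0.5
    ys = np.arange(y0, y1) + 0.5
    gx = np.exp(-((xs - cx_px) ** 2) / (2 * sigma_px ** 2))
    gy = np.exp(-((ys - cy_px) ** 2) / (2 * sigma_px ** 2))
    frame[y0:y1, x0:x1] += peak * gy[:, None] * gx[None, :]


def observable_track_speeds(truth: dict, roi: RoiRect, n_frames: int,
                            min_spots: int = 3) -> pd.Series:
    """True speeds of the ground-truth tracks a windowed analysis can see.

    A track is observable when at least ``min_spots`` of its positions fall
    inside ``roi`` during the first ``n_frames`` frames.  Because fast
    comets exit the region sooner, the observable subset is slower on
    average than the full spawn distribution — comparisons against recovered
    mean speeds must use this subset, mirroring the acquisition protocol.
    """
    pos = truth["positions"]
    pos = pos[pos["frame"] < n_frames]
    inside = pos[(pos["x_um"] >= roi.x0) & (pos["x_um"] < roi.x1)
                 & (pos["y_um"] >= roi.y0) & (pos["y_um"] < roi.y1)]
    counts = inside.groupby("track_id").size()
    seen = counts[counts >= min_spots].index
    return truth["tracks"].set_index("track_id").loc[seen, "speed_um_min"]


# ---------------------------------------------------------------------------
# Region-intensity fixtures


def generate_region_intensity_stack(mhbc_mean: float, midbrain_mean: float,
                                    hindbrain_mean: float,
                                    layout: tuple[RoiRect, RoiRect, RoiRect],
                                    noise_sd: float = 0.0, seed: int = 0,
                                    spacing: tuple = (0.2, 0.2, 0.5),
                                    n_planes: int = 5):
    """Piecewise-constant stack with the stated region means plus noise.

    ``layout`` is (mhbc, midbrain, hindbrain) ROIs in μm; they must be
    pairwise disjoint.  The background outside the ROIs takes the mean of
    the three region means (so equal means give a spatially uniform stack).
    Returns (ImageStack3D, truth dict of the stated means).
    """
    rois = tuple(layout)
    if len(rois) != 3:
        raise ValueError("layout must contain exactly three ROIs")
    for i in range(3):
        for j in range(i + 1, 3):
            if rois[i].overlaps(rois[j]):
                raise ValueError(f"ROIs {i} and {j} overlap")
    means = (float(mhbc_mean), float(midbrain_mean), float(hindbrain_mean))
    sx, sy, sz = spacing
    margin = 2.0
    x_hi = max(r.x1 for r in rois) + margin
    y_hi = max(r.y1 for r in rois) + margin
    nx, ny = int(np.ceil(x_hi / sx)), int(np.ceil(y_hi / sy))
    xc = (np.arange(nx) + 0.5) * sx
    yc = (np.arange(ny) + 0.5) * sy
    X, Y = np.meshgrid(xc, yc)
    plane = np.full((ny, nx), np.mean(means), dtype=np.float64)
    for roi, mean in zip(rois, means):
        sel = (X >= roi.x0) & (X < roi.x1) & (Y >= roi.y0) & (Y < roi.y1)
        plane[sel] = mean
    voxels = np.broadcast_to(plane, (n_planes, ny, nx)).copy()
    if noise_sd > 0:
        rng = np.random.default_rng([seed, 3])
        voxels = voxels + rng.normal(0.0, noise_sd, voxels.shape)
    stack = ImageStack3D(voxels=voxels, spacing=spacing,
                         channel_name="region-fixture")
    truth = {"mhbc_mean": means[0], "midbrain_mean": means[1],
             "hindbrain_mean": means[2]}
    return stack, truth
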