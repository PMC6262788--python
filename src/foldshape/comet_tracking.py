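"""Plus-end comet quantification: preparation, segmentation, detection,
linking and per-track speeds.

The pipeline mirrors a two-branch Fiji workflow: the movie is cropped in
time (200 s) and space (50×40 μm), min-max rescaled to 8-bit; comet *number*
and *size* come from Otsu thresholding plus connected-component particle
analysis, while comet *speed* comes from normalized Laplacian-of-Gaussian
sub-pixel detection followed by predictive linear-motion linking.  After the
fixed quality floor, an automatic Otsu cut on the spot-quality distribution
separates genuine comets from noise maxima (TrackMate's "auto initial
threshold" step), which makes the fixed floor portable across intensity
scales.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .config import PipelineConfig
from .types import CometSpot, CometSummary, CometTrack, RoiRect, TimeLapse2D

log = logging.getLogger(__name__)

__all__ = [
    "prepare_movie",
    "otsu_threshold",
    "segment_particles",
    "detect_log",
    "link_tracks",
    "track_speed",
    "summarize_comets",
]

_EIGHT = np.ones((3, 3), dtype=bool)


def prepare_movie(movie: TimeLapse2D, duration: float = 200.0,
                  roi: RoiRect | None = None) -> TimeLapse2D:
    """Crop to the first ``duration`` seconds and the ROI, rescale to 8-bit.

    The min-max rescaling is computed over the whole retained series so
    frames stay mutually comparable.  A constant-valued movie maps to all
    zeros (degenerate range, logged).
    """
    n_keep = int(np.floor(duration / movie.frame_interval))
    if n_keep > movie.n_frames:
        raise ValueError(
            f"movie of {movie.duration_s:.0f} s is shorter than the "
            f"requested {duration:.0f} s analysis window")
    sx, sy = movie.pixel_spacing
    frames = movie.frames[:n_keep]
    if roi is not None:
        ny, nx = frames.shape[1:]
        if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > nx * sx or roi.y1 > ny * sy:
            raise ValueError(f"ROI {roi} outside the {nx * sx}×{ny * sy} μm field")
        ix0 = int(np.ceil(roi.x0 / sx - 0.5))
        ix1 = int(np.ceil(roi.x1 / sx - 0.5))
        iy0 = int(np.ceil(roi.y0 / sy - 0.5))
        iy1 = int(np.ceil(roi.y1 / sy - 0.5))
        frames = frames[:, iy0:iy1, ix0:ix1]
    frames = frames.astype(np.float64)
    lo, hi = frames.min(), frames.max()
    if hi <= lo:
        log.warning("movie has a degenerate intensity range; output is all zero")
        out = np.zeros_like(frames, dtype=np.uint8)
    else:
        out = np.clip(np.round((frames - lo) / (hi - lo) * 255), 0,
                      255).astype(np.uint8)
    return TimeLapse2D(frames=out, pixel_spacing=movie.pixel_spacing,
                       frame_interval=movie.frame_interval)


def particle_working_image(frame: np.ndarray,
                           pixel_spacing: tuple[float, float],
                           presmooth_um: float = 0.3) -> np.ndarray:
    """The 8-bit image the particle branch thresholds.

    A light Gaussian pre-filter at roughly the comet scale suppresses
    single-pixel noise excursions that would otherwise percolate through a
    global threshold; the result is re-quantized to 8-bit so the Otsu
    histogram stays 256 bins.
    """
    frame = np.asarray(frame)
    if frame.dtype != np.uint8:
        raise ValueError("particle analysis expects an 8-bit frame")
    if presmooth_um <= 0:
        return frame
    sx, sy = pixel_spacing
    smoothed = ndimage.gaussian_filter(frame.astype(np.float64),
                                       (presmooth_um / sy, presmooth_um / sx))
    return np.clip(np.round(smoothed), 0, 255).astype(np.uint8)


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> int | None:
    """Otsu cut index maximizing between-class variance on an n-bin histogram.

    For 8-bit input pass the raw image (bins = intensity levels); the
    returned integer t splits classes as ``value <= t`` / ``value > t``.
    Returns None when the histogram has a single occupied bin.  Ties resolve
    to the smallest t.
    """
    hist = np.bincount(np.asarray(values, dtype=np.intp).ravel(),
                       minlength=n_bins).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        return None
    levels = np.arange(n_bins, dtype=np.float64)
    w0 = np.cumsum(hist)
    sum0 = np.cumsum(hist * levels)
    mu_total = sum0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (mu_total - sum0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return int(np.argmax(sigma_b[:-1]))


def segment_particles(frame: np.ndarray, min_area: float, max_area: float,
                      pixel_spacing: tuple[float, float],
                      presmooth_um: float = 0.3,
                      split_touching: bool = True):
    """Otsu-threshold the 8-bit frame and return particle (centroid, area).

    The threshold is computed and applied on the pre-filtered working image
    (see :func:`particle_working_image`).  Centroids are (x, y) μm; areas
    μm².  Components outside [min_area, max_area] are discarded;
    8-connectivity.
    """
    sx, sy = pixel_spacing
    frame = particle_working_image(frame, pixel_spacing, presmooth_um)
    t = otsu_threshold(frame)
    if t is None:
        log.warning("single-valued frame histogram; no particles")
        return []
    binary = frame > t
    lab, n = ndimage.label(binary, structure=_EIGHT)
    if n == 0:
        return []
    if split_touching:
        lab, n = _watershed_split(frame, binary, pixel_spacing)
        if n == 0:
            return []
    px_area = sx * sy
    counts = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    centroids = ndimage.center_of_mass(binary, lab, np.arange(1, n + 1))
    out = []
    for (cy, cx), cnt in zip(centroids, counts):
        if cnt == 0:
            continue
        area = cnt * px_area
        if min_area <= area <= max_area:
            out.append(((float((cx + 0.5) * sx), float((cy + 0.5) * sy)),
                        float(area)))
    return out


def _watershed_split(work: np.ndarray, binary: np.ndarray,
                     pixel_spacing: tuple[float, float],
                     min_separation_um: float = 0.5):
    """Split touching particles by an intensity watershed.

    Markers are intensity maxima of the working image within the binary
    mask, at least ``min_separation_um`` apart — the particle-analysis
    analogue of the binary watershed step used to separate abutting spots.
    """
    from skimage.segmentation import watershed

    sx, sy = pixel_spacing
    min_dist = max(1, int(round(min_separation_um / max(sx, sy))))
    work = work.astype(np.float64)
    # one marker per connected local-maximum region (a flat plateau — e.g. a
    # saturated or constant-intensity particle — stays a single marker)
    mf = ndimage.maximum_filter(work, size=2 * min_dist + 1)
    maxima = (work == mf) & binary
    markers, n_markers = ndimage.label(maxima, structure=_EIGHT)
    if n_markers == 0:
        return ndimage.label(binary, structure=_EIGHT)
    lab = watershed(-work, markers, mask=binary)
    return lab, n_markers


def detect_log(frame: np.ndarray, pixel_spacing: tuple[float, float],
               blob_diameter: float = 1.0, quality_threshold: float = 0.5,
               subpixel: bool = True, auto_quality: bool = True,
               frame_index: int = 0) -> list[CometSpot]:
    """Normalized-LoG spot detection with sub-pixel localization.

    The response is −σ²∇²(G_σ∗I) with σ = (blob_diameter/2)/√2 (the radius
    of a blob of the stated diameter in scale space).  Local maxima with
    response ≥ quality_threshold are kept; with ``auto_quality`` an Otsu cut
    on the quality distribution of those maxima is applied on top.  Sub-pixel
    refinement fits a 1D parabola through the response along each axis.
    """
    sx, sy = pixel_spacing
    if abs(sx - sy) > 1e-9 * max(sx, sy):
        raise ValueError("LoG detection requires isotropic pixels")
    if blob_diameter < 2 * sx:
        raise ValueError(
            f"blob_diameter {blob_diameter} μm is under two pixels "
            f"({sx} μm/px); undetectable scale")
    sigma_px = (blob_diameter / 2.0) / np.sqrt(2.0) / sx
    img = np.asarray(frame, dtype=np.float64)
    response = -(sigma_px ** 2) * ndimage.gaussian_laplace(img, sigma_px)
    local_max = (response == ndimage.maximum_filter(response, size=3))
    local_max &= response >= quality_threshold
    # a blob centered on a pixel boundary yields a plateau of equal maxima;
    # keep one representative pixel per connected plateau
    plat, n_plat = ndimage.label(local_max, structure=np.ones((3, 3), bool))
    if n_plat:
        all_r, all_c = np.nonzero(local_max)
        order = np.lexsort((all_c, all_r))
        seen = set()
        keep_r, keep_c = [], []
        for k in order:
            lab_id = plat[all_r[k], all_c[k]]
            if lab_id not in seen:
                seen.add(lab_id)
                keep_r.append(all_r[k])
                keep_c.append(all_c[k])
        rr = np.array(keep_r, dtype=int)
        cc = np.array(keep_c, dtype=int)
    else:
        rr = np.array([], dtype=int)
        cc = np.array([], dtype=int)
    qualities = response[rr, cc]
    if auto_quality and len(qualities) > 1:
        qmin, qmax = qualities.min(), qualities.max()
        if qmax > qmin:
            bins = np.clip(((qualities - qmin) / (qmax - qmin) * 255), 0,
                           255).astype(np.intp)
            t = otsu_threshold(bins)
            if t is not None:
                cut = qmin + (t + 0.5) / 256.0 * (qmax - qmin)
                keep = qualities > cut
                rr, cc, qualities = rr[keep], cc[keep], qualities[keep]
    ny, nx = img.shape
    spots = []
    for r, c, q in zip(rr, cc, qualities):
        dy = dx = 0.0
        if subpixel and 0 < r < ny - 1 and 0 < c < nx - 1:
            dy = _parabolic_offset(response[r - 1, c], response[r, c],
                                   response[r + 1, c])
            dx = _parabolic_offset(response[r, c - 1], response[r, c],
                                   response[r, c + 1])
        spots.append(CometSpot(frame=frame_index,
                               position=(float((c + 0.5 + dx) * sx),
                                         float((r + 0.5 + dy) * sy)),
                               quality=float(q)))
    return spots


def _parabolic_offset(left: float, center: float, right: float) -> float:
    denom = left - 2.0 * center + right
    if denom >= 0:  # not a local max in the continuous sense
        return 0.0
    return float(np.clip(0.5 * (left - right) / denom, -0.5, 0.5))


def link_tracks(spots_by_frame: dict[int, list[CometSpot]],
                max_link_radius: float = 1.5, gap_frames: int = 2,
                min_track_length: int = 5,
                frame_interval: float | None = None) -> list[CometTrack]:
    """Predictive linear-motion linking.

    Each open track carries a constant-velocity state (its last step); per
    frame, links between predicted positions and detections within
    ``max_link_radius`` are chosen to minimize the total squared distance to
    the predictions (global assignment).  Unmatched tracks persist up to
    ``gap_frames`` frames before closing; unmatched spots seed new tracks.
    Tracks shorter than ``min_track_length`` spots are discarded.  If
    ``frame_interval`` is given, mean speeds (μm/min) are filled in.
    """
    BIG = 1e12
    open_tracks: list[dict] = []
    closed: list[list[CometSpot]] = []
    for f in sorted(spots_by_frame):
        spots = spots_by_frame[f]
        positions = np.array([s.position for s in spots], dtype=float) \
            if spots else np.empty((0, 2))
        preds = np.array([t["pos"] + t["vel"] * (f - t["frame"])
                          for t in open_tracks], dtype=float) \
            if open_tracks else np.empty((0, 2))
        matched_t, matched_s = set(), set()
        if len(preds) and len(positions):
            d2 = ((preds[:, None, :] - positions[None, :, :]) ** 2).sum(-1)
            cost = np.where(d2 <= max_link_radius ** 2, d2, BIG)
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < BIG:
                    t = open_tracks[i]
                    dt_frames = f - t["frame"]
                    new_pos = positions[j]
                    t["vel"] = (new_pos - t["pos"]) / dt_frames
                    t["pos"] = new_pos
                    t["frame"] = f
                    t["spots"].append(spots[j])
                    matched_t.add(i)
                    matched_s.add(j)
        still_open = []
        for i, t in enumerate(open_tracks):
            if i in matched_t or f - t["frame"] <= gap_frames:
                still_open.append(t)
            else:
                closed.append(t["spots"])
        open_tracks = still_open
        for j, s in enumerate(spots):
            if j not in matched_s:
                open_tracks.append(dict(pos=positions[j],
                                        vel=np.zeros(2), frame=f,
                                        spots=[s]))
    closed.extend(t["spots"] for t in open_tracks)
    tracks = []
    for spots in closed:
        if len(spots) < min_track_length:
            continue
        track = CometTrack(spots=spots)
        if frame_interval is not None:
            track.mean_speed = track_speed(track, frame_interval)
        tracks.append(track)
    return tracks


def track_speed(track: CometTrack, frame_interval: float) -> float:
    """Mean link speed in μm/min over consecutive spot pairs."""
    if len(track.spots) < 2:
        raise ValueError("track speed needs at least two spots")
    speeds = []
    for a, b in zip(track.spots, track.spots[1:]):
        disp = np.hypot(b.position[0] - a.position[0],
                        b.position[1] - a.position[1])
        dt = (b.frame - a.frame) * frame_interval
        speeds.append(disp / dt * 60.0)
    return float(np.mean(speeds))


def summarize_comets(movie: TimeLapse2D,
                     config: PipelineConfig | None = None) -> CometSummary:
    """Per-movie summary of a *prepared* (8-bit) movie.

    Comet number and size come from the Otsu + particle-analysis branch;
    mean speed from the LoG + linear-motion-linking branch (unweighted mean
    over tracks, None when no track survives the length filter).
    """
    config = config or PipelineConfig()
    sx, sy = movie.pixel_spacing
    counts, areas = [], []
    spots_by_frame = {}
    for f in range(movie.n_frames):
        frame = movie.frames[f]
        particles = segment_particles(
            frame, config.particle_min_area_um2,
            config.particle_max_area_um2, movie.pixel_spacing,
            presmooth_um=config.particle_presmooth_um,
            split_touching=config.particle_split_touching)
        counts.append(len(particles))
        areas.extend(a for _, a in particles)
        spots_by_frame[f] = detect_log(
            frame, movie.pixel_spacing,
            blob_diameter=config.blob_diameter_um,
            quality_threshold=config.quality_threshold,
            subpixel=config.subpixel, auto_quality=config.auto_quality,
            frame_index=f)
    tracks = link_tracks(spots_by_frame,
                         max_link_radius=config.max_link_radius_um,
                         gap_frames=config.gap_frames,
                         min_track_length=config.min_track_length,
                         frame_interval=movie.frame_interval)
    mean_speed = float(np.mean([t.mean_speed for t in tracks])) \
        if tracks else None
    return CometSummary(mean_speed=mean_speed,
                        comet_number=float(np.mean(counts)) if counts else 0.0,
                        comet_size=float(np.mean(areas)) if areas else 0.0,
                        n_tracks=len(tracks), n_frames=movie.n_frames)
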