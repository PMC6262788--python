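"""TIFF / CSV I/O for stacks, label volumes, time-lapse movies and result tables.

Stacks are written as ImageJ-style TIFFs: xy pixel size goes into the TIFF
resolution tags and the z spacing (or frame interval) into the ImageJ
metadata block, so files round-trip through Fiji as well as through this
package.  On disk the plane order is (z, y, x) / (t, y, x); in memory the API
speaks the anatomical (x, y, z) convention (see :mod:`foldshape.types`).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .types import (BandQuantification, CellLabelVolume, CometSummary,
                    ImageStack3D, IntensityRatioResult, RoiRect,
                    ShapeMeasurement, TimeLapse2D)

__all__ = [
    "read_stack", "write_stack", "read_labels", "write_labels",
    "read_movie", "write_movie", "write_measurements", "read_measurements",
    "read_roi_csv", "write_roi_csv",
]


# ---------------------------------------------------------------------------
# TIFF helpers


def _write_imagej_tiff(path, data: np.ndarray, sx: float, sy: float, extra: dict):
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"unit": "um", **extra},
    )


def _read_imagej_tiff(path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ij = tf.imagej_metadata or {}
        page = tf.pages[0]
        res = {}
        for axis, tag in (("x", "XResolution"), ("y", "YResolution")):
            t = page.tags.get(tag)
            if t is not None:
                num, den = t.value
                if num:
                    res[axis] = den / num  # μm per pixel
    return data, ij, res


def write_stack(path, stack: ImageStack3D) -> None:
    sx, sy, sz = stack.spacing
    _write_imagej_tiff(path, np.asarray(stack.voxels, dtype=np.float32),
                       sx, sy, {"spacing": sz, "channel": stack.channel_name})


def read_stack(path) -> ImageStack3D:
    """Read a 3D intensity stack; spacing must be present in the metadata."""
    data, ij, res = _read_imagej_tiff(path)
    if data.ndim != 3:
        raise ValueError(f"expected 3 dimensions, got {data.ndim}")
    if "x" not in res or "y" not in res or "spacing" not in ij:
        missing = [k for k in ("XResolution", "YResolution", "ImageJ spacing")
                   if (k == "ImageJ spacing" and "spacing" not in ij)
                   or (k == "XResolution" and "x" not in res)
                   or (k == "YResolution" and "y" not in res)]
        raise ValueError(f"missing voxel-spacing metadata: {', '.join(missing)}")
    spacing = (res["x"], res["y"], float(ij["spacing"]))
    return ImageStack3D(voxels=data, spacing=spacing,
                        channel_name=str(ij.get("channel", "")))


def write_labels(path, labels: CellLabelVolume) -> None:
    sx, sy, sz = labels.spacing
    _write_imagej_tiff(path, np.asarray(labels.labels, dtype=np.uint16),
                       sx, sy, {"spacing": sz})


def read_labels(path) -> CellLabelVolume:
    data, ij, res = _read_imagej_tiff(path)
    if data.ndim != 3:
        raise ValueError(f"expected 3 dimensions, got {data.ndim}")
    if "x" not in res or "spacing" not in ij:
        raise ValueError("missing voxel-spacing metadata: resolution / ImageJ spacing")
    return CellLabelVolume(labels=data.astype(np.int32),
                           spacing=(res["x"], res["y"], float(ij["spacing"])))


def write_movie(path, movie: TimeLapse2D) -> None:
    sx, sy = movie.pixel_spacing
    _write_imagej_tiff(path, np.asarray(movie.frames, dtype=np.float32),
                       sx, sy, {"finterval": movie.frame_interval})


def read_movie(path) -> TimeLapse2D:
    data, ij, res = _read_imagej_tiff(path)
    if data.ndim != 3:
        raise ValueError(f"expected a (t, y, x) series, got {data.ndim} dimensions")
    if "x" not in res or "finterval" not in ij:
        raise ValueError("missing metadata: pixel resolution / ImageJ finterval")
    return TimeLapse2D(frames=data, pixel_spacing=(res["x"], res["y"]),
                       frame_interval=float(ij["finterval"]))


# ---------------------------------------------------------------------------
# Measurement tables

# Fixed column orders; units are spelled in the header names.
_SCHEMAS = {
    ShapeMeasurement: ["cell_id", "surface", "y_position_um", "area_um2",
                       "depth_um", "depth_angle_deg", "width_um", "xz_ratio",
                       "anisotropic"],
    CometSummary: ["mean_speed", "comet_number", "comet_size", "n_tracks",
                   "n_frames"],
    IntensityRatioResult: ["mhbc_mean", "midbrain_mean", "hindbrain_mean",
                           "normalized_mhbc"],
    BandQuantification: ["target_band", "loading_band", "normalized_level",
                         "percent_of_control"],
}


def _record_kind(record):
    for kind in _SCHEMAS:
        if isinstance(record, kind):
            return kind
    raise TypeError(f"unsupported record type {type(record).__name__}")


def write_measurements(records: Sequence, path, kind=None) -> None:
    """Write a homogeneous list of result records as a CSV table.

    ``kind`` must be given for an empty list (to pick the header).
    """
    records = list(records)
    if records:
        kinds = {_record_kind(r) for r in records}
        if len(kinds) > 1:
            raise ValueError(f"mixed record kinds: "
                             f"{sorted(k.__name__ for k in kinds)}")
        kind = kinds.pop()
    elif kind is None:
        raise ValueError("kind is required to write an empty table")
    cols = _SCHEMAS[kind]
    rows = []
    for r in records:
        row = {}
        for c in cols:
            v = getattr(r, c)
            row[c] = v() if callable(v) else v
        rows.append(row)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")


def read_measurements(path, kind) -> list:
    """Re-parse a table written by :func:`write_measurements`."""
    df = pd.read_csv(path)
    cols = _SCHEMAS[kind]
    out = []
    fields = {f.name for f in dataclasses.fields(kind)}
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in cols if c in fields}
        for key, val in list(kwargs.items()):
            if isinstance(val, np.generic):
                kwargs[key] = val.item()
        out.append(kind(**kwargs))
    return out


# ---------------------------------------------------------------------------
# ROI files: name,x_um,y_um,width_um,height_um


def read_roi_csv(path) -> dict[str, RoiRect]:
    df = pd.read_csv(path)
    required = {"name", "x_um", "y_um", "width_um", "height_um"}
    if not required.issubset(df.columns):
        raise ValueError(f"ROI file must have columns {sorted(required)}")
    return {str(r["name"]): RoiRect(origin=(float(r["x_um"]), float(r["y_um"])),
                                    width=float(r["width_um"]),
                                    height=float(r["height_um"]))
            for _, r in df.iterrows()}


def write_roi_csv(path, rois: dict[str, RoiRect]) -> None:
    rows = [{"name": name, "x_um": roi.x0, "y_um": roi.y0,
             "width_um": roi.width, "height_um": roi.height}
            for name, roi in rois.items()]
    pd.DataFrame(rows, columns=["name", "x_um", "y_um", "width_um",
                                "height_um"]).to_csv(path, index=False)
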