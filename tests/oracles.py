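"""Independent brute-force oracles for the chord metrics.

The searches below visit *every* admissible boundary-pixel pair with plain
loops and keep the best under the documented ordering (longest; ties to the
smaller angle / angular deviation; then lexicographically smaller
endpoints).  They share only the supercover insideness rule with the
implementation — that rule is part of the chord definition — while the
search strategy is written independently.
"""

import numpy as np

from foldshape.rasterize import segment_inside


def _boundary(mask):
    out = []
    nr, nc = mask.shape
    for r in range(nr):
        for c in range(nc):
            if not mask[r, c]:
                continue
            if (r == 0 or r == nr - 1 or c == 0 or c == nc - 1
                    or not (mask[r - 1, c] and mask[r + 1, c]
                            and mask[r, c - 1] and mask[r, c + 1])):
                out.append((r, c))
    return out


def _chord_geometry(p0, p1, sx, sz):
    dz = (p1[0] - p0[0]) * sz
    dx = (p1[1] - p0[1]) * sx
    dist = float(np.hypot(dx, dz))
    ux, uz = abs(dx) / dist, abs(dz) / dist
    length = dist + ux * sx + uz * sz
    angle = float(np.degrees(np.arctan2(abs(dx), abs(dz))))
    return length, angle


def brute_depth_chord(mask, spacing, max_angle=45.0):
    """Exhaustive deepest-chord search; returns (length, angle)."""
    sx, sz = spacing
    bps = _boundary(mask)
    best = None
    for i in range(len(bps)):
        for j in range(i + 1, len(bps)):
            p0, p1 = bps[i], bps[j]
            length, angle = _chord_geometry(p0, p1, sx, sz)
            if angle > max_angle + 1e-9:
                continue
            if not segment_inside(mask, p0[0], p0[1], p1[0], p1[1]):
                continue
            key = (-length, angle, p0, p1)
            if best is None or key < best[0]:
                best = (key, length, angle)
    if best is None:
        return float(sz), 0.0
    return best[1], best[2]


def brute_width_perpendicular(mask, spacing, depth_angle, perp_tol=3.0):
    """Exhaustive perpendicular-chord search; returns the length."""
    sx, sz = spacing
    target = 90.0 - depth_angle
    bps = _boundary(mask)
    best = None
    for i in range(len(bps)):
        for j in range(i + 1, len(bps)):
            p0, p1 = bps[i], bps[j]
            length, angle = _chord_geometry(p0, p1, sx, sz)
            dev = abs(angle - target)
            if dev > perp_tol + 1e-9:
                continue
            if not segment_inside(mask, p0[0], p0[1], p1[0], p1[1]):
                continue
            key = (-length, dev, p0, p1)
            if best is None or key < best[0]:
                best = (key, length)
    if best is None:
        t = np.radians(target)
        return float(abs(np.sin(t)) * sx + abs(np.cos(t)) * sz)
    return best[1]
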