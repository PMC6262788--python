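"""Supercover line rasterization on an integer pixel grid.

The supercover of a segment between two pixel centers is the set of every
pixel whose closed unit square the segment touches — a stricter set than a
Bresenham line.  A chord "lies inside" a mask when every supercover pixel is
in the mask; this is the insideness rule used by the chord-metric searches.
"""

from __future__ import annotations

import numpy as np

__all__ = ["supercover_line", "boundary_pixels", "segment_inside"]


def supercover_line(r0: int, c0: int, r1: int, c1: int) -> list[tuple[int, int]]:
    """All grid cells (row, col) touched by the segment between pixel centers.

    When the segment passes exactly through a grid corner, both side cells
    are included (the conservative convention).
    """
    cells = [(r0, c0)]
    dr = r1 - r0
    dc = c1 - c0
    sr = 1 if dr > 0 else -1
    sc = 1 if dc > 0 else -1
    adr, adc = abs(dr), abs(dc)
    r, c = r0, c0
    ir = ic = 0  # borders crossed so far along each axis
    # next row border is crossed at t = (2·ir+1)/(2·adr); comparing the two
    # crossing times with cross-multiplied integers keeps the walk exact.
    while (r, c) != (r1, c1):
        tr = (2 * ir + 1) * adc if adr > 0 else None
        tc = (2 * ic + 1) * adr if adc > 0 else None
        if tc is None or (tr is not None and tr < tc):
            r += sr
            ir += 1
        elif tr is None or tc < tr:
            c += sc
            ic += 1
        else:
            # exact corner: the segment touches all four surrounding cells
            cells.append((r + sr, c))
            cells.append((r, c + sc))
            r += sr
            c += sc
            ir += 1
            ic += 1
        cells.append((r, c))
    return cells


def segment_inside(mask: np.ndarray, r0: int, c0: int, r1: int, c1: int) -> bool:
    """True if every supercover pixel of the segment lies in ``mask``."""
    nr, nc = mask.shape
    for r, c in supercover_line(r0, c0, r1, c1):
        if r < 0 or c < 0 or r >= nr or c >= nc or not mask[r, c]:
            return False
    return True


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """(n, 2) array of (row, col) mask pixels with a 4-neighbor outside.

    Pixels on the image border count as boundary.  Rows are sorted
    lexicographically so downstream tie-breaking is deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = mask & ~interior
    rr, cc = np.nonzero(boundary)
    return np.stack([rr, cc], axis=1)
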