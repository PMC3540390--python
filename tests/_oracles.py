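"""Independent reference implementations used only to cross-check the library.

Each oracle recomputes a quantity by a different route than the library
(direct neighborhood enumeration, breadth-first flood fill, linear-algebra
moment solving, exhaustive threshold scanning) so agreement is evidence of
correctness rather than of shared code.
"""

from collections import deque

import numpy as np


def bernsen_oracle(pixels: np.ndarray, radius: int, contrast: float, bit_depth: int) -> np.ndarray:
    """Brute-force Bernsen: per-pixel disk neighborhood enumeration."""
    rows, cols = pixels.shape
    half = float(2 ** (bit_depth - 1))
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = (dy * dy + dx * dx) <= radius * radius
    out = np.zeros(pixels.shape, dtype=bool)
    for y in range(rows):
        y0, y1 = max(0, y - radius), min(rows, y + radius + 1)
        for x in range(cols):
            x0, x1 = max(0, x - radius), min(cols, x + radius + 1)
            sub = pixels[y0:y1, x0:x1]
            m = disk[
                y0 - (y - radius) : y1 - (y - radius),
                x0 - (x - radius) : x1 - (x - radius),
            ]
            vals = sub[m]
            lmin, lmax = int(vals.min()), int(vals.max())
            mid = (lmax + lmin) / 2.0
            if (lmax - lmin) < contrast:
                out[y, x] = mid >= half
            else:
                out[y, x] = pixels[y, x] >= mid
    return out


def flood_fill_label(mask: np.ndarray, connectivity: int):
    """Scan-order BFS labeling; returns (label_map, areas in label order)."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = mask.shape
    labels = np.zeros(mask.shape, dtype=int)
    areas = []
    next_label = 1
    for y in range(rows):
        for x in range(cols):
            if mask[y, x] and labels[y, x] == 0:
                queue = deque([(y, x)])
                labels[y, x] = next_label
                area = 0
                while queue:
                    cy, cx = queue.popleft()
                    area += 1
                    for oy, ox in offsets:
                        ny, nx = cy + oy, cx + ox
                        if 0 <= ny < rows and 0 <= nx < cols and mask[ny, nx] and labels[ny, nx] == 0:
                            labels[ny, nx] = next_label
                            queue.append((ny, nx))
                areas.append(area)
                next_label += 1
    return labels, areas


def moments_oracle_threshold(pixels: np.ndarray, n_levels: int) -> int:
    """Moment-preserving threshold via linear solve + polynomial roots.

    The two representative gray levels of the bilevel image are the roots of
    ``z**2 + c1*z + c0`` where (c0, c1) solve the linear moment-consistency
    system; the background fraction follows, and the threshold is the gray
    level whose cumulative histogram fraction is closest to it.
    """
    hist = np.bincount(pixels.ravel(), minlength=n_levels).astype(float)
    p = hist / hist.sum()
    levels = np.arange(n_levels, dtype=float)
    m1, m2, m3 = (float(np.sum(levels**k * p)) for k in (1, 2, 3))
    c0, c1 = np.linalg.solve(np.array([[1.0, m1], [m1, m2]]), np.array([-m2, -m3]))
    z0, z1 = np.sort(np.roots([1.0, c1, c0]).real)
    p0 = (z1 - m1) / (z1 - z0)
    cum = np.cumsum(p)
    return int(np.argmin(np.abs(cum - p0)))


def linear_scan_calibration(
    pixels: np.ndarray,
    net_area_cutoff: int,
    connectivity: int,
    tolerated: int,
    max_value: int,
):
    """Exhaustive ascending scan over every integer threshold level."""
    from skimage.measure import label as sklabel

    for t in range(1, max_value + 2):
        if t > max_value:
            return None
        lab, n = sklabel(
            pixels >= t, connectivity=1 if connectivity == 4 else 2, return_num=True
        )
        if n == 0:
            return t
        areas = np.bincount(lab.ravel())[1:]
        if int(np.count_nonzero(areas >= net_area_cutoff)) <= tolerated:
            return t
    return None
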