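"""Patch preprocessing: edge-preserving smoothing and contour extraction.

The pipeline smooths each grayscale patch with a bilateral filter before
feature extraction, and traces the ordered boundary of the nucleus mask for
the contour-irregularity (CCV) statistic.  Coordinates are (col, row) with
the origin at the top-left corner, columns increasing rightwards and rows
downwards; the contour is traced clockwise in that plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class ContourError(ValueError):
    """Mask unsuitable for boundary tracing."""


@dataclass(frozen=True)
class Contour:
    """Ordered closed nucleus boundary.

    ``points`` is an (N, 2) integer array of (col, row) pixel coordinates in
    clockwise traversal order; consecutive points (and, when ``closed``, the
    first/last pair) are 8-adjacent.
    """

    points: np.ndarray
    closed: bool = True

    def __len__(self) -> int:
        return len(self.points)


def bilateral_filter(
    gray: np.ndarray,
    sigma_spatial: float = 3.0,
    sigma_range: float = 25.0,
    win_size: int = 7,
) -> np.ndarray:
    """Edge-preserving bilateral smoothing of an 8-bit grayscale patch.

    ``sigma_range`` is expressed in gray levels on the 0–255 scale.  Returns
    a float image on the same 0–255 scale, bounded by the input min/max.
    """
    gray = np.asarray(gray, dtype=float)
    if gray.size == 0:
        raise ValueError("empty image")
    if sigma_spatial <= 0 or sigma_range <= 0:
        raise ValueError("sigmas must be positive")
    if win_size < 1 or win_size % 2 == 0:
        raise ValueError("win_size must be an odd positive integer")
    radius = win_size // 2
    pad = np.pad(gray, radius, mode="symmetric")
    h, w = gray.shape
    num = np.zeros_like(gray)
    den = np.zeros_like(gray)
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            shifted = pad[radius + di : radius + di + h, radius + dj : radius + dj + w]
            weight = np.exp(
                -(di * di + dj * dj) / (2.0 * sigma_spatial**2)
                - (shifted - gray) ** 2 / (2.0 * sigma_range**2)
            )
            num += weight * shifted
            den += weight
    return num / den


# Moore neighbourhood in clockwise order, (dcol, drow), starting at "up".
_MOORE = [(0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1)]


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ContourError("mask must be 2-d")
    labels, n = ndimage.label(mask)  # 4-connectivity
    if n == 0:
        raise ContourError("mask has no foreground component")
    if n > 1:
        raise ContourError(f"mask has {n} foreground components; expected 1")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise ContourError("foreground touches the image border")
    return mask


def trace_contour(mask: np.ndarray) -> Contour:
    """Trace the ordered clockwise boundary of a single-component mask.

    Moore-neighbour tracing with Jacob's stopping criterion, starting from
    the topmost of the leftmost foreground pixels, whose left neighbour is
    guaranteed background.
    """
    mask = _validate_mask(mask)
    cols_any = np.flatnonzero(mask.any(axis=0))
    start_col = int(cols_any[0])
    start_row = int(np.flatnonzero(mask[:, start_col])[0])
    start = (start_col, start_row)

    if mask.sum() == 1:
        return Contour(points=np.array([start], dtype=int))

    def fg(p):
        return mask[p[1], p[0]]

    # State: current pixel p and backtrack direction (index into _MOORE
    # pointing from p to the background pixel entered from).  The start's
    # left neighbour is background by choice of start pixel.  The walk is
    # deterministic, so it is eventually periodic; the boundary is the
    # cycle, detected by the first repeated (pixel, backtrack) state.
    points = [start]
    p, dir_back = start, 6  # 6 == (-1, 0), "left"
    seen = {(p, dir_back): 0}
    while True:
        q = None
        for k in range(1, 9):
            d = (dir_back + k) % 8
            cand = (p[0] + _MOORE[d][0], p[1] + _MOORE[d][1])
            if fg(cand):
                # the neighbour scanned just before cand is background and
                # 8-adjacent to cand: it becomes the new backtrack pixel
                prev = (d - 1) % 8
                b = (p[0] + _MOORE[prev][0], p[1] + _MOORE[prev][1])
                new_back = _MOORE.index((b[0] - cand[0], b[1] - cand[1]))
                q = cand
                break
        if q is None:  # isolated pixel; unreachable after the size-1 check
            break
        state = (q, new_back)
        if state in seen:
            points = points[seen[state]:]
            break
        seen[state] = len(points)
        points.append(q)
        p, dir_back = q, new_back
    # canonical start: rotate the cycle to begin at the topmost-leftmost pixel
    if start in points and points[0] != start:
        k = points.index(start)
        points = points[k:] + points[:k]
    return Contour(points=np.array(points, dtype=int))
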