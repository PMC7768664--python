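"""Shared low-level geometry helpers (points are float ``(row, col)`` arrays)."""

from __future__ import annotations

import numpy as np


def unit(v: np.ndarray) -> np.ndarray:
    """Normalize a 2-vector; raises on (near-)zero length."""
    v = np.asarray(v, dtype=float)
    n = float(np.hypot(v[0], v[1]))
    if n < 1e-12:
        raise ValueError("zero-length vector has no direction")
    return v / n


def angle_between(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two vectors, in radians within [0, pi]."""
    u = unit(u)
    v = unit(v)
    return float(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0)))


def rotate(v: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate a (row, col) vector by ``degrees`` (counter-clockwise in col-x/row-y
    image coordinates, i.e. visually clockwise on screen — consistent everywhere)."""
    a = np.deg2rad(degrees)
    c, s = np.cos(a), np.sin(a)
    r, col = float(v[0]), float(v[1])
    # rotate in (x=col, y=row) plane
    x, y = col, r
    return np.array([s * x + c * y, c * x - s * y])


def line_intersection(p: np.ndarray, d1: np.ndarray, q: np.ndarray, d2: np.ndarray):
    """Intersection of lines p + s*d1 and q + t*d2, or None when near-parallel."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    if abs(denom) < 1e-9 * max(1.0, float(np.hypot(*d1)) * float(np.hypot(*d2))):
        return None
    w = q - p
    s = (w[0] * d2[1] - w[1] * d2[0]) / denom
    return p + s * d1


def point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point in ``pts`` (Q,2) to segment a-b."""
    pts = np.atleast_2d(np.asarray(pts, float))
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-18:
        return np.hypot(*(pts - a).T)
    t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.hypot(*(pts - proj).T)


def point_polyline_distance(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Minimum distance from each query point to an open polyline (P,2)."""
    poly = np.atleast_2d(np.asarray(poly, float))
    pts = np.atleast_2d(np.asarray(pts, float))
    if len(poly) == 1:
        return np.hypot(*(pts - poly[0]).T)
    best = np.full(len(pts), np.inf)
    for a, b in zip(poly[:-1], poly[1:]):
        np.minimum(best, point_segment_distance(pts, a, b), out=best)
    return best


# Moore neighborhood in clockwise order starting from "west" (image convention:
# row grows downward), used by the boundary tracer.
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Trace the outer contour of one 8-connected component, clockwise.

    Moore contour following with Jacob's stopping criterion, starting at the
    topmost-leftmost foreground pixel. Returns an ordered (K,2) int array of
    boundary pixels. A fixed convention so downstream breakpoint ordering is
    reproducible.
    """
    mask = np.asarray(mask, bool)
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise ValueError("empty mask has no boundary")
    i = int(np.argmin(rows * mask.shape[1] + cols))  # topmost, then leftmost
    start = (int(rows[i]), int(cols[i]))
    if len(rows) == 1:
        return np.array([start])

    def fg(p):
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    contour = [start]
    # backtrack point: the pixel we "came from"; start scanning from west
    prev = (start[0], start[1] - 1)
    cur = start
    first_next = None
    for _ in range(8 * len(rows) + 8):
        dr, dc = prev[0] - cur[0], prev[1] - cur[1]
        k = _MOORE.index((dr, dc))
        nxt = None
        for j in range(1, 9):
            cand_off = _MOORE[(k + j) % 8]
            cand = (cur[0] + cand_off[0], cur[1] + cand_off[1])
            if fg(cand):
                nxt = cand
                prev = (cur[0] + _MOORE[(k + j - 1) % 8][0],
                        cur[1] + _MOORE[(k + j - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            break
        if cur == start and first_next is None:
            first_next = nxt
        elif cur == start and nxt == first_next:
            break  # Jacob's criterion: re-entered start the same way
        contour.append(nxt)
        cur = nxt
    if len(contour) > 1 and contour[-1] == start:
        contour.pop()
    return np.array(contour, dtype=int)
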