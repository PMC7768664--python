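"""Breakpoint recognition and matching around damaged regions.

Every ridge terminus adjacent to a damaged region becomes a breakpoint
carrying a tangent estimated a few steps back along its ridge. Breakpoints
are split into two groups by cutting the region's boundary contour at its two
most distant points, ordered along the contour, and paired by minimizing the
total angular mismatch score phi under an order-preservation (no-crossing)
constraint.

The phi score between breakpoints p1, p2 with back-tangents a1, a2 and the
connecting directions a3 = unit(p2-p1), a4 = -a3:

    phi = 2*pi - ang(a1,a3) - ang(a2,a4)              if ang(a1,a2) > theta
    phi = max(pi - ang(a1,a3), pi - ang(a2,a4))       otherwise

with theta = 165 degrees by default; smaller phi means a more plausible
connection (0 for collinear, mutually facing fragments).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage as ndi

from ._geometry import angle_between, unit
from .bezier import Ridge
from .damage import RegionMask


@dataclass
class MatchConfig:
    theta: float = 165.0        # deg; tangent-angle branch point of phi
    k_tangent: int = 5          # steps back along the ridge for the tangent
    phi_max: float = np.pi / 2  # rad; pairs above this are implausible
    smooth_window: int = 5      # steps; secant window for unsmoothness
    turn_min: float = 25.0      # deg; minimum turning angle for a latent bif
    breakpoint_gap: float = 2.0  # px; max endpoint distance to the region

    def __post_init__(self):
        if not 0 < self.theta < 180:
            raise ValueError("theta must lie in (0, 180) degrees")
        if self.k_tangent < 2:
            raise ValueError("k_tangent must be >= 2")


@dataclass
class Breakpoint:
    pos: np.ndarray             # ridge terminus (row, col)
    ridge_id: int
    tangent: np.ndarray         # unit, from pos back along the ridge
    neighbor: np.ndarray        # point k steps back along the ridge
    side: str = "?"             # "A" | "B"
    order_idx: int = -1
    at_start: bool = True       # terminus == ridge.points[0]?

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        self.neighbor = np.asarray(self.neighbor, dtype=float)
        self.tangent = unit(np.asarray(self.tangent, dtype=float))


@dataclass
class MatchPair:
    start: Breakpoint
    end: Breakpoint
    phi: float
    kind: str = "plain"         # "plain" | "to-latent-bifurcation" | "marginal"


def ridge_tangent(points: np.ndarray, from_start: bool, k: int = 5) -> tuple:
    """(tangent, neighbor): averaged secant over steps 3..k to damp jitter."""
    pts = np.asarray(points, dtype=float)
    if not from_start:
        pts = pts[::-1]
    kk = min(k, len(pts) - 1)
    steps = [s for s in range(3, kk + 1)] or [kk]
    vecs = [unit(pts[s] - pts[0]) for s in steps if np.hypot(*(pts[s] - pts[0])) > 1e-9]
    if not vecs:
        raise ValueError("degenerate ridge end: no tangent")
    return unit(np.mean(vecs, axis=0)), pts[kk]


def _boundary_split(boundary: np.ndarray) -> tuple[int, int]:
    """Indices of the two most distant contour points (the group split)."""
    pts = boundary.astype(float)
    n = len(pts)
    if n <= 2:
        return 0, n // 2
    step = max(1, n // 256)          # cap O(n^2) on huge contours
    sub = pts[::step]
    d = ((sub[:, None, :] - sub[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    i, j = sorted((int(i) * step, int(j) * step))
    return i, j


def find_breakpoints(ridges: list[Ridge], region: RegionMask,
                     cfg: MatchConfig | None = None) -> list[Breakpoint]:
    """Breakpoints of ``region``: ridge ends within reach of the damage mask.

    Sides are assigned by splitting the boundary contour at its two extremal
    points into arcs A and B; ``order_idx`` ranks each breakpoint by its
    nearest boundary pixel along the arc so both sides run in the same
    spatial direction (rank 0 nearest the first split point).
    """
    cfg = cfg or MatchConfig()
    dist = ndi.distance_transform_edt(~region.mask)
    boundary = region.boundary
    i1, i2 = _boundary_split(boundary)
    K = len(boundary)

    bps = []
    for r in ridges:
        if r.is_loop:
            continue
        for from_start in (True, False):
            pos = r.points[0] if from_start else r.points[-1]
            if dist[pos[0], pos[1]] > cfg.breakpoint_gap:
                continue
            try:
                tangent, neighbor = ridge_tangent(r.points, from_start, cfg.k_tangent)
            except ValueError:
                continue
            bps.append(Breakpoint(pos=pos, ridge_id=r.ridge_id, tangent=tangent,
                                  neighbor=neighbor, at_start=from_start))
    if not bps:
        return []

    for bp in bps:
        d2 = ((boundary.astype(float) - bp.pos) ** 2).sum(1)
        j = int(np.argmin(d2))
        on_a = (j - i1) % K <= (i2 - i1) % K
        bp.side = "A" if on_a else "B"
        bp._rank = (j - i1) % K if on_a else (i1 - j) % K

    for side in ("A", "B"):
        group = sorted([b for b in bps if b.side == side], key=lambda b: b._rank)
        for idx, b in enumerate(group):
            b.order_idx = idx
    return bps


def phi_score(b1: Breakpoint, b2: Breakpoint, cfg: MatchConfig | None = None) -> float:
    """Angular mismatch of connecting b1 to b2 (radians, >= 0, symmetric)."""
    cfg = cfg or MatchConfig()
    if np.allclose(b1.pos, b2.pos):
        raise ValueError("breakpoints coincide")
    a1, a2 = b1.tangent, b2.tangent
    a3 = unit(b2.pos - b1.pos)
    a4 = -a3
    ang12 = np.rad2deg(angle_between(a1, a2))
    ang13 = angle_between(a1, a3)
    ang24 = angle_between(a2, a4)
    if ang12 > cfg.theta:
        phi = 2 * np.pi - ang13 - ang24
    else:
        phi = max(np.pi - ang13, np.pi - ang24)
    return max(float(phi), 0.0)


def match_region(side_a: list[Breakpoint], side_b: list[Breakpoint],
                 cfg: MatchConfig | None = None):
    """Order-preserving pairing minimizing total phi.

    Dynamic programming over alignments of the two order_idx-sorted groups:
    maximize the number of pairs with phi <= phi_max, then minimize the total
    phi among those (lexicographic). Returns (pairs, forwarded) where
    ``forwarded`` are the breakpoints left unmatched (candidates for
    latent-bifurcation search or marginal matching).
    """
    cfg = cfg or MatchConfig()
    A = sorted(side_a, key=lambda b: b.order_idx)
    B = sorted(side_b, key=lambda b: b.order_idx)
    n, m = len(A), len(B)
    if n == 0 or m == 0:
        return [], list(A) + list(B)

    cost = np.full((n, m), np.inf)
    for i in range(n):
        for j in range(m):
            try:
                p = phi_score(A[i], B[j], cfg)
            except ValueError:
                continue
            if p <= cfg.phi_max:
                cost[i, j] = p

    # dp[i][j] = best (-(pairs), total_phi) using A[:i], B[:j]
    INF = (0, 0.0)
    dp = [[(0, 0.0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = min(dp[i - 1][j], dp[i][j - 1])
            if np.isfinite(cost[i - 1, j - 1]):
                pr, tot = dp[i - 1][j - 1]
                best = min(best, (pr - 1, tot + cost[i - 1, j - 1]))
            dp[i][j] = best

    pairs = []
    i, j = n, m
    while i > 0 and j > 0:
        if dp[i][j] == dp[i - 1][j]:
            i -= 1
        elif dp[i][j] == dp[i][j - 1]:
            j -= 1
        else:
            pairs.append(MatchPair(A[i - 1], B[j - 1], float(cost[i - 1, j - 1])))
            i -= 1
            j -= 1
    pairs.reverse()
    matched = {id(p.start) for p in pairs} | {id(p.end) for p in pairs}
    forwarded = [b for b in A + B if id(b) not in matched]
    return pairs, forwarded


def find_latent_bifurcation(edge_ridge: Ridge, opposite: Breakpoint,
                            cfg: MatchConfig | None = None):
    """Best unsmooth point of a region-adjacent ridge, or None.

    Candidate points turn by more than ``turn_min`` degrees over the secant
    window; among them the one minimizing distance-to-opposite / turning-angle
    wins (close and sharply bent beats far and gently bent).
    """
    cfg = cfg or MatchConfig()
    pts = np.asarray(edge_ridge.points, dtype=float)
    w = cfg.smooth_window
    if len(pts) < 2 * w + 1:
        return None
    best = None
    best_score = np.inf
    for i in range(w, len(pts) - w):
        v1 = pts[i] - pts[i - w]
        v2 = pts[i + w] - pts[i]
        if np.hypot(*v1) < 1e-9 or np.hypot(*v2) < 1e-9:
            continue
        turn = np.rad2deg(angle_between(v1, v2))
        if turn <= cfg.turn_min:
            continue
        d = float(np.hypot(*(pts[i] - opposite.pos)))
        score = d / turn
        if score < best_score:
            best_score = score
            best = pts[i]
    return None if best is None else best.astype(int)


def marginal_match(breakpoints: list[Breakpoint], p1, p2,
                   n: int | None = None) -> list[MatchPair]:
    """Pair breakpoints with uniform bisection points of the segment p1-p2.

    Targets sit at fractions i/(n+1), i = 1..n along p1 -> p2 and are paired
    with the breakpoints in ``order_idx`` order. Each target becomes a
    synthetic breakpoint whose tangent continues the straight approach, so
    candidate generation treats it like a ridge end beyond the margin.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.allclose(p1, p2):
        raise ValueError("marginal endpoints coincide")
    bps = sorted(breakpoints, key=lambda b: b.order_idx)
    n = n if n is not None else len(bps)
    if n < 1 or n != len(bps):
        raise ValueError("n must equal the number of breakpoints")
    pairs = []
    for i, bp in enumerate(bps, start=1):
        target = p1 + (p2 - p1) * (i / (n + 1))
        if np.hypot(*(target - bp.pos)) < 1e-9:
            approach = -bp.tangent  # target on the breakpoint: continue straight
        else:
            approach = unit(target - bp.pos)
        synth = Breakpoint(pos=target, ridge_id=-1, tangent=approach,
                           neighbor=target + 3 * approach,
                           side="B" if bp.side == "A" else "A", order_idx=i - 1)
        try:
            phi = phi_score(bp, synth)
        except ValueError:
            phi = 0.0
        pairs.append(MatchPair(bp, synth, phi, kind="marginal"))
    return pairs
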