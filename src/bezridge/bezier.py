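"""Ridge extraction and cubic-Bezier modeling of fingerprint skeletons.

A skeleton is decomposed into individual ridges by walking its pixel graph
with 8-connectivity; each ridge is fitted with one or more cubic Bezier spans
(Schneider-style least squares with fixed endpoints and chord-length
parameterization). The four control points per span are the compressed
representation; rasterizing them back reproduces the skeleton.

Coordinates are (row, col), 0-based, pixel centers at integers. The ``.bez``
text serialization writes x=col, y=row to match image-viewer convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage as ndi

from ._geometry import angle_between
from .preprocess import remove_2x2_blocks


@dataclass
class Ridge:
    """One traced skeleton path; consecutive points are 8-neighbors."""

    points: np.ndarray  # (N, 2) int, (row, col)
    ridge_id: int = -1
    is_loop: bool = False
    junction_a: tuple | None = None  # junction pixel shared at the first point
    junction_b: tuple | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=int)
        n = len(self.points)
        if self.is_loop:
            if n < 4:
                raise ValueError("loop ridge needs at least 4 points")
        elif n < 2:
            raise ValueError("ridge needs at least 2 points")
        steps = np.abs(np.diff(self.points, axis=0))
        if steps.size and steps.max() > 1:
            raise ValueError("consecutive ridge points must be 8-neighbors")

    @property
    def endpoint_a(self) -> np.ndarray:
        return self.points[0]

    @property
    def endpoint_b(self) -> np.ndarray:
        return self.points[-1]

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class BezierSegment:
    """One cubic span: endpoints p0/p3, interior control points p1/p2."""

    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray

    def __post_init__(self):
        for name in ("p0", "p1", "p2", "p3"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def control_array(self) -> np.ndarray:
        return np.stack([self.p0, self.p1, self.p2, self.p3])

    def reversed(self) -> "BezierSegment":
        return BezierSegment(self.p3, self.p2, self.p1, self.p0)


@dataclass
class FitConfig:
    """Ridge-fitting knobs: split tolerance, corner angle, minimum length."""

    max_fit_error: float = 1.0     # px; split until polycurve is this close
    corner_angle: float = 100.0    # deg; interior angles below this split first
    min_ridge_len: int = 4         # px; shorter ridges get a degenerate span

    def __post_init__(self):
        if self.max_fit_error <= 0:
            raise ValueError("max_fit_error must be positive")
        if not 90.0 <= self.corner_angle <= 180.0:
            raise ValueError("corner_angle must lie in [90, 180] degrees")


@dataclass
class CurveRecord:
    curve_id: int
    spans: list
    branch_of: int | None = None


@dataclass
class FingerprintModel:
    """All fitted curves of one fingerprint plus raster dimensions."""

    width: int
    height: int
    curves: list = field(default_factory=list)
    provenance: str = ""

    def add_curve(self, spans: Sequence[BezierSegment], branch_of: int | None = None) -> int:
        cid = len(self.curves)
        self.curves.append(CurveRecord(cid, list(spans), branch_of))
        return cid

    def n_spans(self) -> int:
        return sum(len(c.spans) for c in self.curves)


def eval_bezier(seg: BezierSegment, t) -> np.ndarray:
    """De-Casteljau-free closed form; t may be scalar or array in [0, 1]."""
    t = np.asarray(t, dtype=float)
    if np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
        raise ValueError("parameter t must lie in [0, 1]")
    t = np.clip(t, 0.0, 1.0)
    u = 1.0 - t
    pts = (u**3)[..., None] * seg.p0 + 3 * (u**2 * t)[..., None] * seg.p1 \
        + 3 * (u * t**2)[..., None] * seg.p2 + (t**3)[..., None] * seg.p3
    return pts


def bezier_second_derivative(seg: BezierSegment, t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    a = seg.p2 - 2 * seg.p1 + seg.p0
    b = seg.p3 - 2 * seg.p2 + seg.p1
    return 6 * (1 - t)[..., None] * a + 6 * t[..., None] * b


_NB8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    k = np.ones((3, 3), dtype=int)
    k[1, 1] = 0
    return ndi.convolve(skel.astype(int), k, mode="constant")


def extract_ridges(skel: np.ndarray) -> list[Ridge]:
    """Split a skeleton into ridges terminating at endpoints and junctions.

    Endpoints have one 8-neighbor; junction pixels (>= 3 neighbors) terminate
    every incident ridge and are shared between them, so bifurcation structure
    stays recoverable. Pure cycles come back as ``is_loop`` ridges. Isolated
    single pixels are dropped (a one-pixel path is not a ridge).
    """
    skel = np.asarray(skel).astype(bool)
    counts = _neighbor_counts(skel)
    H, W = skel.shape
    is_node = skel & ((counts == 1) | (counts >= 3))

    def neighbors(r, c):
        for dr, dc in _NB8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < H and 0 <= cc < W and skel[rr, cc]:
                yield rr, cc

    ridges: list[Ridge] = []
    used_edges: set = set()
    visited_mid = np.zeros_like(skel)

    def walk(start, first):
        """Follow degree-2 pixels from ``start`` through ``first`` to a node."""
        path = [start, first]
        prev, cur = start, first
        while not is_node[cur] and skel[cur[0], cur[1]]:
            visited_mid[cur] = True
            nxts = [p for p in neighbors(*cur) if p != prev]
            if len(nxts) == 0:
                break
            if len(nxts) > 1:
                # prefer a 4-neighbor continuation to avoid diagonal shortcuts
                nxts.sort(key=lambda p: (abs(p[0] - cur[0]) + abs(p[1] - cur[1]),
                                         p))
                nxts = [n for n in nxts if n != prev]
            prev, cur = cur, nxts[0]
            path.append(cur)
            if cur == start:  # cycle through a node-free ring guard
                break
        return path

    node_list = [tuple(p) for p in zip(*np.nonzero(is_node))]
    for node in node_list:
        for nb in neighbors(*node):
            edge_key = (node, nb)
            if edge_key in used_edges:
                continue
            path = walk(node, nb)
            end = path[-1]
            used_edges.add((node, nb))
            if len(path) >= 2:
                used_edges.add((end, path[-2]))
            if len(path) < 2:
                continue
            ja = node if is_node[node] and counts[node] >= 3 else None
            jb = end if (0 <= end[0] < H and is_node[end] and counts[end] >= 3) else None
            ridges.append(Ridge(np.array(path), ridge_id=len(ridges),
                                junction_a=ja, junction_b=jb))

    # remaining untouched degree-2 pixels belong to pure cycles
    leftover = skel & ~visited_mid & ~is_node & (counts == 2)
    for r, c in zip(*np.nonzero(leftover)):
        if not leftover[r, c]:
            continue
        cycle = [(r, c)]
        prev, cur = None, (r, c)
        while True:
            leftover[cur] = False
            nxts = [p for p in neighbors(*cur) if p != prev]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
            if cur == (r, c):
                break
            cycle.append(cur)
        if len(cycle) >= 4:
            ridges.append(Ridge(np.array(cycle), ridge_id=len(ridges), is_loop=True))

    return ridges


def prune_skeleton(skel: np.ndarray, min_branch_len: int = 6) -> np.ndarray:
    """Remove spur branches and fragments shorter than ``min_branch_len``.

    A spur is a ridge with at least one free end (not a junction) shorter
    than the threshold; tiny isolated fragments are dropped entirely. The
    remaining ridges are redrawn, so the output satisfies the skeleton
    invariants again.
    """
    skel = np.asarray(skel).astype(bool)
    ridges = extract_ridges(skel)
    out = np.zeros_like(skel)
    for r in ridges:
        free_end = r.junction_a is None or r.junction_b is None
        if not r.is_loop and free_end and len(r) < min_branch_len:
            continue
        out[r.points[:, 0], r.points[:, 1]] = True
    return remove_2x2_blocks(out).astype(np.uint8)


def _chord_params(points: np.ndarray) -> np.ndarray:
    d = np.hypot(*np.diff(points, axis=0).T)
    u = np.concatenate([[0.0], np.cumsum(d)])
    total = u[-1]
    return u / total if total > 0 else np.linspace(0, 1, len(points))


def _fit_cubic_fixed_ends(points: np.ndarray, u: np.ndarray) -> BezierSegment:
    """Least-squares interior control points with endpoints pinned."""
    p0, p3 = points[0], points[-1]
    b0 = (1 - u) ** 3
    b1 = 3 * (1 - u) ** 2 * u
    b2 = 3 * (1 - u) * u**2
    b3 = u**3
    rhs = points - np.outer(b0, p0) - np.outer(b3, p3)
    A = np.stack([b1, b2], axis=1)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return BezierSegment(p0, sol[0], sol[1], p3)


def _newton_reparam(seg: BezierSegment, points: np.ndarray, u: np.ndarray) -> np.ndarray:
    """One Newton step moving each parameter toward its closest curve point."""
    c = seg.control_array()
    d1 = 3 * np.diff(c, axis=0)          # quadratic derivative control points
    d2 = 2 * np.diff(d1, axis=0)
    t = u
    b = eval_bezier(seg, t)
    # derivative at t
    v = (1 - t)[:, None] ** 2 * d1[0] + 2 * ((1 - t) * t)[:, None] * d1[1] + (t**2)[:, None] * d1[2]
    a = (1 - t)[:, None] * d2[0] + t[:, None] * d2[1]
    diff = b - points
    num = np.einsum("ij,ij->i", diff, v)
    den = np.einsum("ij,ij->i", v, v) + np.einsum("ij,ij->i", diff, a)
    step = np.where(np.abs(den) > 1e-12, num / np.where(np.abs(den) > 1e-12, den, 1.0), 0.0)
    t2 = np.clip(t - step, 0.0, 1.0)
    t2[0], t2[-1] = 0.0, 1.0
    return np.maximum.accumulate(t2)


def _fit_errors(seg: BezierSegment, points: np.ndarray, u: np.ndarray) -> np.ndarray:
    return np.hypot(*(eval_bezier(seg, u) - points).T)


def _tdm_refit(seg: BezierSegment, points: np.ndarray, u: np.ndarray) -> BezierSegment:
    """Tangent-distance refit of the interior control points.

    Minimizes only the normal component of the residual at the current
    footpoints, which removes the flat tangential-sliding directions that
    stall plain alternating least squares and recovers the generating cubic
    of exactly-sampled data.
    """
    c = seg.control_array()
    d1c = 3 * np.diff(c, axis=0)
    t = u
    v = (1 - t)[:, None] ** 2 * d1c[0] + 2 * ((1 - t) * t)[:, None] * d1c[1] \
        + (t**2)[:, None] * d1c[2]
    speed = np.hypot(v[:, 0], v[:, 1])
    ok = speed > 1e-9
    n = np.zeros_like(v)
    n[ok] = np.stack([-v[ok, 1], v[ok, 0]], axis=1) / speed[ok, None]
    b0 = (1 - t) ** 3
    b1 = 3 * (1 - t) ** 2 * t
    b2 = 3 * (1 - t) * t**2
    b3 = t**3
    # residual n . (b1*p1 + b2*p2 - rhs) with rhs = x - b0*p0 - b3*p3
    rhs_pts = points - np.outer(b0, seg.p0) - np.outer(b3, seg.p3)
    A = np.stack([b1 * n[:, 0], b1 * n[:, 1], b2 * n[:, 0], b2 * n[:, 1]], axis=1)
    rhs = np.einsum("ij,ij->i", n, rhs_pts)
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    return BezierSegment(seg.p0, sol[0:2], sol[2:4], seg.p3)


def _polish_geometric(seg: BezierSegment, pts: np.ndarray, u: np.ndarray,
                      err0: float):
    from scipy.optimize import least_squares

    p0, p3 = seg.p0, seg.p3

    def resid(x):
        cand = BezierSegment(p0, x[:2], x[2:], p3)
        uu = u.copy()
        for _ in range(4):
            uu = _newton_reparam(cand, pts, uu)
        return _fit_errors(cand, pts, uu)

    def finish(x):
        cand = BezierSegment(p0, x[:2], x[2:], p3)
        uu = u.copy()
        for _ in range(6):
            uu = _newton_reparam(cand, pts, uu)
        return cand, uu, float(_fit_errors(cand, pts, uu).max())

    x0 = np.concatenate([seg.p1, seg.p2])
    try:
        if err0 < 0.05:
            # already near-exact: only sampled-curve data gets here, and the
            # flat valley needs the full budget to pin the controls
            sol = least_squares(resid, x0, xtol=1e-12, ftol=1e-14,
                                gtol=1e-12, max_nfev=100)
            cand, uu, err = finish(sol.x)
        else:
            # short probe: pixelated data sits on its quantization floor and
            # gains nothing, while exact samples collapse quickly toward zero
            probe = least_squares(resid, x0, xtol=1e-12, ftol=1e-14,
                                  gtol=1e-12, max_nfev=12)
            cand, uu, err = finish(probe.x)
            if err < 0.25 * err0 or err < 0.05:
                sol = least_squares(resid, probe.x, xtol=1e-12, ftol=1e-14,
                                    gtol=1e-12, max_nfev=60)
                cand, uu, err = finish(sol.x)
    except Exception:
        return seg, u, err0
    if err < err0:
        return cand, uu, err
    return seg, u, err0


def _corner_indices(points: np.ndarray, corner_angle_deg: float, win: int = 3) -> list[int]:
    """Interior indices where the path turns sharply (secant angle test)."""
    n = len(points)
    out = []
    thresh = np.deg2rad(corner_angle_deg)
    for i in range(win, n - win):
        v1 = points[i] - points[i - win]
        v2 = points[i + win] - points[i]
        if np.hypot(*v1) < 1e-9 or np.hypot(*v2) < 1e-9:
            continue
        interior = np.pi - angle_between(v1, v2)
        if interior < thresh:
            out.append(i)
    # collapse runs of adjacent corner indices to their middle
    collapsed = []
    run = []
    for i in out:
        if run and i != run[-1] + 1:
            collapsed.append(run[len(run) // 2])
            run = []
        run.append(i)
    if run:
        collapsed.append(run[len(run) // 2])
    return collapsed


def _fit_recursive(points: np.ndarray, cfg: FitConfig, depth: int = 0) -> list[BezierSegment]:
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3 or depth > 24:
        p0, p3 = pts[0], pts[-1]
        return [BezierSegment(p0, p0 + (p3 - p0) / 3, p0 + 2 * (p3 - p0) / 3, p3)]
    # two canonical parameterization starts: chord length (natural for pixel
    # chains) and uniform index (exact for curves sampled uniformly in t)
    u = _chord_params(pts)
    seg = _fit_cubic_fixed_ends(pts, u)
    errs = _fit_errors(seg, pts, u)
    u_uni = np.linspace(0.0, 1.0, len(pts))
    seg_uni = _fit_cubic_fixed_ends(pts, u_uni)
    errs_uni = _fit_errors(seg_uni, pts, u_uni)
    if errs_uni.max() < errs.max():
        u, seg, errs = u_uni, seg_uni, errs_uni
    # alternate Newton reparameterization and least-squares refit. The
    # residual valley is very flat in the control points, so exact-cubic
    # inputs need many (cheap) iterations to recover the generating controls;
    # pixelated ridges hit their noise floor and stop after a few.
    best_seg, best_u, best_err = seg, u, float(errs.max())
    stall = 0
    for _ in range(12):
        for _ in range(2):
            u = _newton_reparam(seg, pts, u)
        # take whichever refit helps more; TDM converges fast near the
        # optimum but can diverge from afar, where plain least squares is safe
        cand_t = _tdm_refit(seg, pts, u)
        cand_p = _fit_cubic_fixed_ends(pts, u)
        err_t = float(_fit_errors(cand_t, pts, u).max())
        err_p = float(_fit_errors(cand_p, pts, u).max())
        seg, err = (cand_t, err_t) if err_t <= err_p else (cand_p, err_p)
        if err < best_err - 1e-9:
            best_seg, best_u, best_err = seg, u, err
            stall = 0
        else:
            stall += 1
        if best_err < 1e-6 or stall >= 3:
            break
    if 1e-6 <= best_err < 0.6:
        # near-exact data: the alternation can stall in the flat tangential
        # valley; a short full least-squares polish (footpoints recomputed
        # inside the residual) pins the generating control points
        best_seg, best_u, best_err = _polish_geometric(best_seg, pts, best_u,
                                                       best_err)
    seg, u = best_seg, best_u
    errs = _fit_errors(seg, pts, u)
    if errs.max() <= cfg.max_fit_error:
        return [seg]
    split = int(np.argmax(errs))
    split = min(max(split, 1), len(pts) - 2)
    return _fit_recursive(pts[: split + 1], cfg, depth + 1) + \
        _fit_recursive(pts[split:], cfg, depth + 1)


def fit_ridge(r: Ridge, cfg: FitConfig | None = None) -> list[BezierSegment]:
    """Fit one ridge with cubic spans sharing endpoints with the pixel path.

    Splits first at sharp corners, then by recursive bisection at the point
    of maximum residual until every pixel lies within ``max_fit_error`` of
    the polycurve. Ridges shorter than ``min_ridge_len`` collapse to a
    degenerate span with control points on the endpoints.
    """
    cfg = cfg or FitConfig()
    pts = np.asarray(r.points, dtype=float)
    if r.is_loop:
        # splice the loop open at its topmost pixel; fit the two halves
        top = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])
        pts = np.roll(pts, -top, axis=0)
        pts = np.vstack([pts, pts[:1]])
        half = len(pts) // 2
        return fit_open_path(pts[: half + 1], cfg) + fit_open_path(pts[half:], cfg)
    return fit_open_path(pts, cfg)


def fit_open_path(pts: np.ndarray, cfg: FitConfig | None = None) -> list[BezierSegment]:
    cfg = cfg or FitConfig()
    pts = np.asarray(pts, dtype=float)
    if len(pts) < cfg.min_ridge_len:
        p0, p3 = pts[0], pts[-1]
        return [BezierSegment(p0, p0, p3, p3)]
    corners = _corner_indices(pts, cfg.corner_angle)
    bounds = [0] + corners + [len(pts) - 1]
    spans: list[BezierSegment] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b <= a:
            continue
        spans.extend(_fit_recursive(pts[a: b + 1], cfg))
    return spans


def model_from_skeleton(skel: np.ndarray, cfg: FitConfig | None = None,
                        provenance: str = "") -> FingerprintModel:
    """Compress a skeleton: trace ridges, fit each, quantize to 0.1 px."""
    cfg = cfg or FitConfig()
    skel = np.asarray(skel).astype(bool)
    model = FingerprintModel(width=skel.shape[1], height=skel.shape[0],
                             provenance=provenance)
    ridges = extract_ridges(skel)
    junction_owner: dict = {}
    for r in ridges:
        spans = [BezierSegment(*np.round(s.control_array(), 1)) for s in fit_ridge(r, cfg)]
        branch_of = None
        for j in (r.junction_a, r.junction_b):
            if j is not None and j in junction_owner:
                branch_of = junction_owner[j]
                break
        cid = model.add_curve(spans, branch_of)
        for j in (r.junction_a, r.junction_b):
            if j is not None and j not in junction_owner:
                junction_owner[j] = cid
    return model


def rasterize(model: FingerprintModel) -> np.ndarray:
    """Draw every span back onto a raster and re-enforce skeleton width.

    Parameter stepping is adaptive: sampling density scales with the span's
    polyline length so consecutive drawn pixels are 8-neighbors.
    """
    out = np.zeros((model.height, model.width), dtype=bool)
    for curve in model.curves:
        for seg in curve.spans:
            coarse = eval_bezier(seg, np.linspace(0, 1, 17))
            length = float(np.hypot(*np.diff(coarse, axis=0).T).sum())
            n = max(int(np.ceil(length * 3)) + 2, 2)
            pts = np.round(eval_bezier(seg, np.linspace(0, 1, n))).astype(int)
            valid = (pts[:, 0] >= 0) & (pts[:, 0] < model.height) \
                & (pts[:, 1] >= 0) & (pts[:, 1] < model.width)
            out[pts[valid, 0], pts[valid, 1]] = True
    return remove_2x2_blocks(out).astype(np.uint8)


# --------------------------------------------------------------------------
# .bez text serialization


def serialize(model: FingerprintModel) -> str:
    """Write a model in the ``.bez`` text format (one decimal place)."""
    lines = [f"BEZ1 {model.width} {model.height}"]
    for curve in model.curves:
        for idx, seg in enumerate(curve.spans):
            coords = []
            for p in (seg.p0, seg.p1, seg.p2, seg.p3):
                coords.append(f"{p[1]:.1f} {p[0]:.1f}")  # x=col, y=row
            line = f"{curve.curve_id} {idx} " + " ".join(coords)
            if idx == 0 and curve.branch_of is not None:
                line += f" #branch_of={curve.branch_of}"
            lines.append(line)
    return "\n".join(lines) + "\n"


class BezParseError(ValueError):
    def __init__(self, lineno: int, msg: str):
        super().__init__(f"line {lineno}: {msg}")
        self.lineno = lineno


def parse(stream: str | Iterable[str]) -> FingerprintModel:
    """Parse the ``.bez`` format; exact round trip with :func:`serialize`."""
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = [ln.rstrip("\n") for ln in stream]
    if not lines:
        raise BezParseError(1, "empty stream")
    header = lines[0].split()
    if len(header) != 3 or header[0] != "BEZ1":
        raise BezParseError(1, f"bad header {lines[0]!r}")
    try:
        width, height = int(header[1]), int(header[2])
    except ValueError:
        raise BezParseError(1, "width/height must be integers") from None
    model = FingerprintModel(width=width, height=height)
    curves: dict[int, CurveRecord] = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        branch_of = None
        if "#branch_of=" in line:
            line, _, tag = line.partition("#branch_of=")
            try:
                branch_of = int(tag.strip())
            except ValueError:
                raise BezParseError(lineno, f"bad branch_of tag {tag!r}") from None
        toks = line.split()
        if len(toks) != 10:
            raise BezParseError(lineno, f"expected 10 fields, got {len(toks)}")
        try:
            cid, span_idx = int(toks[0]), int(toks[1])
            vals = [float(t) for t in toks[2:]]
        except ValueError:
            raise BezParseError(lineno, "malformed numeric field") from None
        pts = [np.array([vals[2 * i + 1], vals[2 * i]]) for i in range(4)]  # y,x -> row,col
        seg = BezierSegment(*pts)
        if cid not in curves:
            curves[cid] = CurveRecord(cid, [], branch_of)
        elif branch_of is not None:
            curves[cid].branch_of = branch_of
        if span_idx != len(curves[cid].spans):
            raise BezParseError(lineno, f"span index {span_idx} out of order")
        curves[cid].spans.append(seg)
    model.curves = [curves[k] for k in sorted(curves)]
    return model
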