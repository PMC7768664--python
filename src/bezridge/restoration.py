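"""Bezier restoration of matched breakpoints and bifurcated ridges.

For each matched pair a grid of candidate cubic curves is generated: the
end tangent lines L1, L2 of the two fragments are rotated by small angles,
their intersection Q found, and control points placed at several fractions of
the E->Q distance. Candidates are ranked with the delta spacing metric

    delta = sum_{i=1..n} ( |s_i - (s_n - s_1)*i/n - s_1|
                         + |d_i - (d_n - d_1)*i/n - d_1| )

where s_i / d_i are minimum distances from the i-th sample of the candidate
(at t = i/n) to the prior / subsequent neighbor ridge. delta = 0 when the
candidate keeps perfectly linear spacing against both flanks; the sweep
proceeds across the region one pair at a time, each chosen curve becoming the
next pair's prior neighbor.

Bifurcations get special handling: a broken branch reconnects to a latent
bifurcation point with a curve whose first control point coincides with that
point (free junction tangent), and a bifurcation covered by the damage is
re-estimated via an auxiliary isosceles right triangle (right angle at the
main track's neighbor point, circumcenter at its breakpoint).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from ._geometry import line_intersection, point_polyline_distance, rotate, unit
from .bezier import (BezierSegment, FingerprintModel, FitConfig, Ridge,
                     bezier_second_derivative, eval_bezier, model_from_skeleton)
from .damage import RegionMask, detect_all
from .matching import (Breakpoint, MatchConfig, MatchPair, find_breakpoints,
                       find_latent_bifurcation, marginal_match, match_region)


@dataclass
class RestoreConfig:
    fractions: list = dc_field(default_factory=lambda: [0.25, 0.5, 0.75, 1.0])
    rotations: list = dc_field(default_factory=lambda: [-20.0, -10.0, 0.0, 10.0, 20.0])
    n_samples: int = 5           # n of the delta metric

    def __post_init__(self):
        if any(f == 0 for f in self.fractions):
            raise ValueError("fractions must exclude 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass
class CandidateCurve:
    seg: BezierSegment
    rot1: float
    rot2: float
    f1: float
    f2: float
    is_reference: bool = False


def _max_curvature(seg: BezierSegment, n: int = 50) -> float:
    t = np.linspace(0, 1, n)
    return float(np.hypot(*bezier_second_derivative(seg, t).T).max())


def generate_candidates(pair: MatchPair, cfg: RestoreConfig | None = None) -> list[CandidateCurve]:
    """Candidate restoration curves for one matched pair.

    L1 and L2 run through each breakpoint and its ridge neighbor; rotating
    them explores non-smooth junctions, and control points at fractions of
    the distance to the intersection Q explore curvature. When the rotated
    lines are parallel (no Q) the control points fall back to one third of
    the endpoint gap along each rotated direction. The rot=0 candidate of
    minimal curvature is flagged as the reference.
    """
    cfg = cfg or RestoreConfig()
    E1, E2 = pair.start.pos, pair.end.pos
    # direction each fragment would continue into the gap
    d1 = unit(E1 - pair.start.neighbor)
    d2 = unit(E2 - pair.end.neighbor)
    gap = float(np.hypot(*(E2 - E1)))
    cands = []
    for rot1 in cfg.rotations:
        dir1 = rotate(d1, rot1)
        for rot2 in cfg.rotations:
            dir2 = rotate(d2, rot2)
            Q = line_intersection(E1, dir1, E2, dir2)
            for f1 in cfg.fractions:
                for f2 in cfg.fractions:
                    if Q is None:
                        C1 = E1 + f1 * (gap / 3.0) * dir1
                        C2 = E2 + f2 * (gap / 3.0) * dir2
                    else:
                        C1 = E1 + f1 * (Q - E1)
                        C2 = E2 + f2 * (Q - E2)
                    cands.append(CandidateCurve(BezierSegment(E1, C1, C2, E2),
                                                rot1, rot2, f1, f2))
    ref_pool = [c for c in cands if c.rot1 == 0 and c.rot2 == 0] or cands
    ref = min(ref_pool, key=lambda c: _max_curvature(c.seg))
    ref.is_reference = True
    return cands


def delta_from_sequences(s, d) -> float:
    """The delta metric on precomputed distance sequences s_i, d_i (i=1..n).

    Each sequence is compared against the linear baseline s_1 + (s_n-s_1)*i/n;
    note the baseline does not interpolate s_1 at i=1 (its i=n term is always
    zero), which is kept exactly as defined. Adding a constant to a whole
    sequence leaves its contribution unchanged.
    """
    s = np.asarray(s, dtype=float)
    d = np.asarray(d, dtype=float)
    if s.shape != d.shape or s.ndim != 1 or len(s) < 2:
        raise ValueError("s and d must be equal-length sequences, n >= 2")
    n = len(s)
    i = np.arange(1, n + 1)
    ds = np.abs(s - (s[-1] - s[0]) * i / n - s[0])
    dd = np.abs(d - (d[-1] - d[0]) * i / n - d[0])
    return float(np.sum(ds + dd))


def delta_score(cand: CandidateCurve | BezierSegment, prior: np.ndarray,
                subsequent: np.ndarray, n: int = 5) -> float:
    """Spacing-consistency score of a candidate against its two flanks."""
    if n < 2:
        raise ValueError("n must be >= 2")
    seg = cand.seg if isinstance(cand, CandidateCurve) else cand
    prior = np.atleast_2d(np.asarray(prior, dtype=float))
    subsequent = np.atleast_2d(np.asarray(subsequent, dtype=float))
    if prior.size == 0 or subsequent.size == 0:
        raise ValueError("prior and subsequent polylines must be non-empty")
    t = np.arange(1, n + 1) / n
    samples = eval_bezier(seg, t)
    s = point_polyline_distance(samples, prior)
    d = point_polyline_distance(samples, subsequent)
    return delta_from_sequences(s, d)


def sample_segment(seg: BezierSegment, n: int = 24) -> np.ndarray:
    return eval_bezier(seg, np.linspace(0, 1, n))


def restore_region(region: RegionMask, pairs: list[MatchPair],
                   context_ridges: list[np.ndarray] | None = None,
                   cfg: RestoreConfig | None = None) -> list[BezierSegment]:
    """Choose one restoration curve per pair, sweeping side to side.

    ``context_ridges`` are polylines of intact ridges near the region; the
    nearest one flanking the first pair is the initial prior, and the nearest
    distinct one flanking the last pair closes the sweep. While sweeping, the
    yet-unrepaired neighbor is stood in for by its reference candidate. With
    no intact flank at all, every pair falls back to its reference candidate.
    """
    cfg = cfg or RestoreConfig()
    if not pairs:
        return []
    pairs = sorted(pairs, key=lambda p: p.start.order_idx)
    cand_sets = [generate_candidates(p, cfg) for p in pairs]
    refs = [next(c for c in cs if c.is_reference) for cs in cand_sets]
    ref_lines = [sample_segment(r.seg) for r in refs]

    def midpoint(p):
        return (p.start.pos + p.end.pos) / 2.0

    prior_flank = subsequent_flank = None
    if context_ridges:
        m0, m1 = midpoint(pairs[0]), midpoint(pairs[-1])
        d0 = [float(point_polyline_distance(m0[None, :], poly)[0]) for poly in context_ridges]
        prior_flank = context_ridges[int(np.argmin(d0))]
        if len(context_ridges) > 1:
            d1 = [float(point_polyline_distance(m1[None, :], poly)[0])
                  if poly is not prior_flank else np.inf for poly in context_ridges]
            if np.isfinite(min(d1)):
                subsequent_flank = context_ridges[int(np.argmin(d1))]
        if subsequent_flank is None:
            subsequent_flank = prior_flank

    if prior_flank is None:
        return [r.seg for r in refs]

    chosen: list[BezierSegment] = []
    prior = prior_flank
    for k, cands in enumerate(cand_sets):
        subsequent = ref_lines[k + 1] if k + 1 < len(cand_sets) else subsequent_flank
        best = min(cands, key=lambda c: delta_score(c, prior, subsequent, cfg.n_samples))
        chosen.append(best.seg)
        prior = sample_segment(best.seg)
    return chosen


def restore_latent_bifurcation(bif, b2: Breakpoint, cfg: RestoreConfig | None = None,
                               branches: list[np.ndarray] | None = None,
                               fraction: float | None = None) -> BezierSegment:
    """Reconnect a broken branch to a surviving (latent) bifurcation point.

    The bifurcation point serves as both endpoint E1 and control point C1,
    freeing the junction tangent; C2 sits on the extension of the broken
    branch beyond its breakpoint at ``fraction`` of the endpoint gap
    (delta-selected against the two branch polylines when given).
    """
    cfg = cfg or RestoreConfig()
    E1 = np.asarray(bif, dtype=float)
    E2 = b2.pos
    d2 = unit(E2 - b2.neighbor)  # continuation of R2 beyond E2, into the gap
    gap = float(np.hypot(*(E2 - E1)))

    def make(f):
        return BezierSegment(E1, E1, E2 + f * gap * d2, E2)

    if fraction is not None:
        return make(fraction)
    if branches:
        best_f = min(cfg.fractions,
                     key=lambda f: delta_score(make(f), branches[0],
                                               branches[-1], cfg.n_samples))
        return make(best_f)
    return make(1.0 / 3.0)


def _triangle_controls(anchor: np.ndarray, apex_from: np.ndarray):
    """Hypotenuse vertices of the isosceles right triangle.

    Right angle at ``apex_from`` (the P3 role), circumcenter at ``anchor``
    (the E3 role): the two hypotenuse vertices are anchor +- R*u with
    R = |anchor - apex_from| and u perpendicular to that leg.
    """
    v = np.asarray(anchor, float) - np.asarray(apex_from, float)
    R = float(np.hypot(*v))
    if R < 1e-9:
        raise ValueError("degenerate triangle: P3 coincides with E3")
    u = unit(np.array([-v[1], v[0]]))
    return anchor + R * u, anchor - R * u


def _branch_control(E: np.ndarray, P: np.ndarray, target: np.ndarray) -> np.ndarray:
    d = unit(E - P)
    return E + (float(np.hypot(*(target - E))) / 3.0) * d


def restore_internal_bifurcation(b1: Breakpoint, b2: Breakpoint, b3: Breakpoint,
                                 cfg: RestoreConfig | None = None):
    """Restore a bifurcation fully covered by the damage.

    b3 is the main-track breakpoint (E3), b1/b2 the branch breakpoints.
    Step 1 treats E3 itself as the bifurcation: an isosceles right triangle
    with the right angle at P3 and circumcenter at E3 supplies the shared
    tangent (its hypotenuse) and the two control points C3a, C3b; temporary
    curves l1, l2 join the branches to E3. Step 2 moves the estimate to the
    midpoint of the midpoints of l1, l2, extends the main track straight to
    that point, and rebuilds the curves with a fresh triangle anchored there
    (with E3 in the P3 role). Returns ([l1, l2, extension], estimated point).
    """
    cfg = cfg or RestoreConfig()
    E1, P1 = b1.pos, b1.neighbor
    E2, P2 = b2.pos, b2.neighbor
    E3, P3 = b3.pos, b3.neighbor

    def side_match(Ca, Cb, Ebranch, anchor):
        # give each branch the hypotenuse vertex on its own side
        return (Ca, Cb) if np.dot(Ca - anchor, Ebranch - anchor) >= \
            np.dot(Cb - anchor, Ebranch - anchor) else (Cb, Ca)

    # step 1: assume E3 is the bifurcation point
    C3a, C3b = _triangle_controls(E3, P3)
    C3a, C3b = side_match(C3a, C3b, E1, E3)
    l1 = BezierSegment(E1, _branch_control(E1, P1, E3), C3a, E3)
    l2 = BezierSegment(E2, _branch_control(E2, P2, E3), C3b, E3)
    Ma = eval_bezier(l1, 0.5)
    Mb = eval_bezier(l2, 0.5)
    est = (Ma + Mb) / 2.0

    if np.hypot(*(est - E3)) < 1e-6:
        return [l1, l2], est

    # step 2: extend the main track to the estimate and rebuild there
    third = (est - E3) / 3.0
    extension = BezierSegment(E3, E3 + third, E3 + 2 * third, est)
    C3a2, C3b2 = _triangle_controls(est, E3)
    C3a2, C3b2 = side_match(C3a2, C3b2, E1, est)
    l1f = BezierSegment(E1, _branch_control(E1, P1, est), C3a2, est)
    l2f = BezierSegment(E2, _branch_control(E2, P2, est), C3b2, est)
    return [l1f, l2f, extension], est


# --------------------------------------------------------------------------
# full-image orchestration


def _ridge_polyline(r: Ridge) -> np.ndarray:
    return np.asarray(r.points, dtype=float)


def restore_fingerprint(skel: np.ndarray, match_cfg: MatchConfig | None = None,
                        restore_cfg: RestoreConfig | None = None,
                        fit_cfg: FitConfig | None = None,
                        regions: list[RegionMask] | None = None):
    """Detect damage, match breakpoints, restore, and merge.

    Returns (model, restored skeleton, report). The model holds the fitted
    original ridges plus the chosen restoration curves; the restored skeleton
    keeps every original pixel verbatim and adds the rasterized restoration
    curves clipped to the damaged neighborhoods. Unrepairable regions are
    recorded in the report, never fatal.
    """
    from skimage.morphology import dilation  # local: cheap import

    match_cfg = match_cfg or MatchConfig()
    restore_cfg = restore_cfg or RestoreConfig()
    fit_cfg = fit_cfg or FitConfig()
    skel = np.asarray(skel).astype(bool)
    if regions is None:
        regions = detect_all(skel)
    from .bezier import extract_ridges
    ridges = extract_ridges(skel)
    report = {"regions": len(regions), "restored_pairs": 0, "skipped": 0,
              "bifurcations": 0, "per_region": []}

    model = model_from_skeleton(skel, fit_cfg, provenance="restore_fingerprint")
    new_segments: list[BezierSegment] = []

    for region in regions:
        info = {"flavor": region.flavor, "pairs": 0, "marginal": 0, "bif": 0}
        try:
            bps = find_breakpoints(ridges, region, match_cfg)
        except ValueError:
            report["skipped"] += 1
            continue
        if not bps:
            report["skipped"] += 1
            continue
        side_a = [b for b in bps if b.side == "A"]
        side_b = [b for b in bps if b.side == "B"]
        broken_ids = {b.ridge_id for b in bps}
        context = []
        for r in ridges:
            if r.ridge_id in broken_ids or r.is_loop:
                continue
            poly = _ridge_polyline(r)
            d = point_polyline_distance(region.centroid[None, :], poly)[0]
            if d < 2.0 * _region_scale(region) and len(poly) >= 4:
                context.append((d, poly))
        context.sort(key=lambda t: t[0])
        context_polys = [p for _, p in context[:6]]

        segs: list[BezierSegment] = []
        pairs, forwarded = match_region(side_a, side_b, match_cfg)
        if forwarded and region.flavor == "interior":
            # a leftover breakpoint whose best partner is already matched
            # signals a covered bifurcation: one main track, two branches
            pairs, forwarded, bif_jobs = _promote_bifurcations(
                pairs, forwarded, side_a, side_b, match_cfg)
            for branch1, branch2, main in bif_jobs:
                try:
                    curves, _est = restore_internal_bifurcation(
                        branch1, branch2, main, restore_cfg)
                except ValueError:
                    continue
                segs.extend(curves)
                info["bif"] += 1
                report["bifurcations"] += 1
        segs.extend(restore_region(region, pairs, context_polys, restore_cfg))
        info["pairs"] = len(pairs)
        report["restored_pairs"] += len(pairs)
        if forwarded:
            if region.flavor == "marginal":
                handled = _restore_marginal(forwarded, region, context_polys,
                                            restore_cfg, segs)
                info["marginal"] = handled
            else:
                for bp in forwarded:
                    seg = _try_latent(bp, ridges, region, match_cfg,
                                      restore_cfg, broken_ids)
                    if seg is not None:
                        segs.append(seg)
                        info["bif"] += 1
                        report["bifurcations"] += 1
        new_segments.extend(segs)
        report["per_region"].append(info)

    for seg in new_segments:
        model.add_curve([BezierSegment(*np.round(seg.control_array(), 1))])

    restored = skel.copy()
    if new_segments and regions:
        allowed = np.zeros_like(skel)
        for region in regions:
            allowed |= dilation(region.mask, np.ones((5, 5), bool))
        patch_model = FingerprintModel(width=skel.shape[1], height=skel.shape[0])
        for seg in new_segments:
            patch_model.add_curve([seg])
        from .bezier import rasterize
        drawn = rasterize(patch_model).astype(bool)
        restored |= drawn & allowed
    return model, restored.astype(np.uint8), report


def _promote_bifurcations(pairs, forwarded, side_a, side_b, match_cfg):
    """Upgrade plain pairs to covered-bifurcation jobs.

    A forwarded breakpoint that scores well (phi <= phi_max) against a
    breakpoint already claimed by a matched pair means one starting point
    corresponds to two ending points: the claimed breakpoint is the main
    track E3 and the two opposite breakpoints are the branches. The plain
    pair is withdrawn and a bifurcation job emitted instead.
    """
    from .matching import phi_score

    jobs = []
    remaining_fwd = []
    pairs = list(pairs)
    for f in forwarded:
        opposite = side_b if f.side == "A" else side_a
        best, best_phi = None, np.inf
        for cand in opposite:
            try:
                p = phi_score(f, cand, match_cfg)
            except ValueError:
                continue
            if p < best_phi:
                best, best_phi = cand, p
        claimed = None
        if best is not None and best_phi <= match_cfg.phi_max:
            for pr in pairs:
                if pr.start is best or pr.end is best:
                    claimed = pr
                    break
        if claimed is None:
            remaining_fwd.append(f)
            continue
        other = claimed.end if claimed.start is best else claimed.start
        pairs = [p for p in pairs if p is not claimed]
        jobs.append((other, f, best))  # (branch1, branch2, main track)
    return pairs, remaining_fwd, jobs


def _restore_marginal(forwarded, region, context_polys, restore_cfg, segs_out) -> int:
    """Marginal bisection matching for breakpoints with no partner."""
    boundary = region.boundary.astype(float)
    if len(boundary) < 2 or not forwarded:
        return 0
    d = ((boundary[:, None, :] - boundary[None, :, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    p1, p2 = boundary[int(i)], boundary[int(j)]
    try:
        pairs = marginal_match(forwarded, p1, p2)
    except ValueError:
        return 0
    chosen = restore_region(region, pairs, context_polys, restore_cfg)
    segs_out.extend(chosen)
    return len(pairs)


def _try_latent(bp, ridges, region, match_cfg, restore_cfg, broken_ids):
    """Search nearby intact ridges for a latent bifurcation point for ``bp``."""
    best = None
    best_d = np.inf
    for r in ridges:
        if r.ridge_id == bp.ridge_id or r.is_loop:
            continue
        # only ridges hugging the damaged region qualify as edge-ridges
        poly = _ridge_polyline(r)
        d = point_polyline_distance(bp.pos[None, :], poly)[0]
        if d > 3.0 * _region_scale(region):
            continue
        pt = find_latent_bifurcation(r, bp, match_cfg)
        if pt is None:
            continue
        dd = float(np.hypot(*(pt - bp.pos)))
        if dd < best_d:
            best_d = dd
            best = pt
    if best is None:
        return None
    return restore_latent_bifurcation(best, bp, restore_cfg)


def _region_scale(region: RegionMask) -> float:
    r0, c0, r1, c1 = region.bbox
    return max(r1 - r0, c1 - c0, 1)
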