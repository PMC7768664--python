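"""Breakpoint recognition, the phi matching score, and pairing."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bezridge.bezier import Ridge, extract_ridges
from bezridge.damage import detect_interior_regions
from bezridge.matching import (Breakpoint, MatchConfig, find_breakpoints,
                               find_latent_bifurcation, marginal_match,
                               match_region, phi_score)
from bezridge.synthgen import ablate, disk_mask, grating_skeleton


def bp(pos, tangent, order=0, side="A", neighbor=None):
    pos = np.asarray(pos, float)
    tangent = np.asarray(tangent, float)
    if neighbor is None:
        neighbor = pos + 4 * tangent
    return Breakpoint(pos=pos, ridge_id=0, tangent=tangent, neighbor=neighbor,
                      side=side, order_idx=order)


class TestPhiScore:
    def test_collinear_facing_fragments_score_zero(self):
        b1 = bp((0, 0), (-1, 0))
        b2 = bp((10, 0), (1, 0))
        assert phi_score(b1, b2) == pytest.approx(0.0, abs=1e-9)

    def test_offset_antiparallel_hand_value(self):
        # same fragments, second one displaced 2 px off-axis:
        # both correction angles are 168.69 deg, phi = 2*pi - 2*2.94420
        b1 = bp((0, 0), (-1, 0))
        b2 = bp((10, 2), (1, 0))
        expect = 2 * np.pi - 2 * (np.pi - np.arctan2(2, 10))
        assert phi_score(b1, b2) == pytest.approx(expect, abs=1e-9)
        assert phi_score(b1, b2) == pytest.approx(0.39479112, abs=1e-6)

    def test_perpendicular_fragments_score_pi_over_two(self):
        b1 = bp((0, 0), (-1, 0))
        b2 = bp((10, 0), (0, 1))
        assert phi_score(b1, b2) == pytest.approx(np.pi / 2, abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10**6))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        p1, p2 = rng.uniform(-20, 20, (2, 2))
        if np.allclose(p1, p2):
            p2 = p1 + (1.0, 0.0)
        t1, t2 = rng.normal(size=(2, 2))
        b1 = bp(p1, t1 / np.linalg.norm(t1))
        b2 = bp(p2, t2 / np.linalg.norm(t2))
        assert phi_score(b1, b2) == pytest.approx(phi_score(b2, b1), abs=1e-12)

    def test_zero_only_when_collinear_and_facing(self):
        # facing but offset, or parallel-not-facing, must not score 0
        assert phi_score(bp((0, 0), (-1, 0)), bp((10, 1), (1, 0))) > 1e-9
        assert phi_score(bp((0, 0), (1, 0)), bp((10, 0), (1, 0))) > 1e-9
        assert phi_score(bp((0, 0), (-1, 0)), bp((10, 0), (1, 0))) <= 1e-9

    def test_monotone_in_lateral_offset(self):
        d = 12.0
        phis = []
        for h in np.linspace(0, 6, 13):
            b1 = bp((0, 0), (0, -1))   # fragments along the column axis
            b2 = bp((h, d), (0, 1))
            phis.append(phi_score(b1, b2))
        assert all(b >= a - 1e-12 for a, b in zip(phis, phis[1:]))

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            phi_score(bp((1, 1), (1, 0)), bp((1, 1), (-1, 0)))


def brute_force_pairs(A, B, cfg):
    """Exhaustive optimum over order-preserving pairings (oracle)."""
    best = (0, 0.0, [])
    idx_a = range(len(A))
    for k in range(min(len(A), len(B)), -1, -1):
        for sub_a in itertools.combinations(idx_a, k):
            for sub_b in itertools.combinations(range(len(B)), k):
                tot = 0.0
                ok = True
                for i, j in zip(sub_a, sub_b):
                    p = phi_score(A[i], B[j], cfg)
                    if p > cfg.phi_max:
                        ok = False
                        break
                    tot += p
                if ok and (-k, tot) < (-best[0], best[1] if best[0] else np.inf):
                    best = (k, tot, list(zip(sub_a, sub_b)))
        if best[0] == k and k > 0:
            break
    return best


class TestMatchRegion:
    def _slit_fixture(self):
        sk = grating_skeleton((64, 64), 8)
        sk[:, 30:34] = 0
        ridges = extract_ridges(sk)
        regions = detect_interior_regions(sk, min_region_area=20)
        if not regions:
            regions = detect_interior_regions(sk, min_gap=5, min_region_area=20)
        return sk, ridges, regions

    def test_parallel_slit_identity_pairing(self):
        cfg = MatchConfig()
        rows = [12, 20, 28, 36, 44]
        A = [bp((r, 30), (0, -1), order=i, side="A") for i, r in enumerate(rows)]
        B = [bp((r, 40), (0, 1), order=i, side="B") for i, r in enumerate(rows)]
        pairs, fwd = match_region(A, B, cfg)
        assert len(pairs) == 5 and not fwd
        for p in pairs:
            assert p.start.order_idx == p.end.order_idx
            assert p.phi < 0.2

    def test_matches_brute_force_on_random_instances(self):
        cfg = MatchConfig()
        for seed in range(12):
            rng = np.random.default_rng(seed)
            na, nb = rng.integers(1, 6, size=2)
            A = [bp(rng.uniform(0, 40, 2), (0, -1), order=i, side="A")
                 for i in range(na)]
            B = [bp(rng.uniform(0, 40, 2), (0, 1), order=i, side="B")
                 for i in range(nb)]
            pairs, _ = match_region(A, B, cfg)
            k, tot, _ = brute_force_pairs(A, B, cfg)
            assert len(pairs) == k
            assert sum(p.phi for p in pairs) == pytest.approx(tot, abs=1e-9)

    def test_no_crossing_pairs(self):
        cfg = MatchConfig()
        rng = np.random.default_rng(7)
        A = [bp((10 * i, 0), (0, -1), order=i, side="A") for i in range(5)]
        B = [bp((10 * i + rng.uniform(-3, 3), 12), (0, 1), order=i, side="B")
             for i in range(5)]
        pairs, _ = match_region(A, B, cfg)
        ranks = [(p.start.order_idx, p.end.order_idx) for p in pairs]
        for (i1, j1), (i2, j2) in itertools.combinations(ranks, 2):
            assert (i1 - i2) * (j1 - j2) > 0

    def test_unequal_sides_forward_leftover(self):
        cfg = MatchConfig()
        A = [bp((10, 0), (0, -1), 0, "A"), bp((20, 0), (0, -1), 1, "A"),
             bp((30, 0), (0, -1), 2, "A")]
        B = [bp((10, 12), (0, 1), 0, "B"), bp((30, 12), (0, 1), 1, "B")]
        pairs, fwd = match_region(A, B, cfg)
        assert len(pairs) == 2
        assert len(fwd) == 1 and fwd[0].pos[0] == 20

    def test_empty_side_forwards_everything(self):
        A = [bp((10, 0), (0, -1), 0, "A")]
        pairs, fwd = match_region(A, [], MatchConfig())
        assert pairs == [] and fwd == A


class TestFindBreakpoints:
    def test_slit_grating_sides_and_order(self):
        # five parallel ridges cut by a vertical slit; region given directly
        from bezridge._geometry import trace_boundary
        from bezridge.damage import RegionMask
        sk = np.zeros((48, 96), np.uint8)
        for r in range(4, 44, 8):
            sk[r, 4:92] = 1
        sk[:, 44:52] = 0
        region_mask = np.zeros_like(sk, bool)
        region_mask[0:48, 43:53] = True
        regions = [RegionMask(mask=region_mask, boundary=trace_boundary(region_mask),
                              flavor="interior", bbox=(0, 43, 47, 52))]
        ridges = extract_ridges(sk)
        bps = find_breakpoints(ridges, regions[0])
        sides = {s: sorted(b.pos[0] for b in bps if b.side == s) for s in "AB"}
        assert len(sides["A"]) == len(sides["B"]) >= 5
        # order_idx follows spatial order identically on both sides
        for s in "AB":
            group = sorted((b for b in bps if b.side == s), key=lambda b: b.order_idx)
            rows = [b.pos[0] for b in group]
            assert rows == sorted(rows) or rows == sorted(rows, reverse=True)
        ga = sorted((b for b in bps if b.side == "A"), key=lambda b: b.order_idx)
        gb = sorted((b for b in bps if b.side == "B"), key=lambda b: b.order_idx)
        assert [a.pos[0] for a in ga] == [b.pos[0] for b in gb]

    def test_single_cut_ridge_antiparallel_tangents(self):
        sk = np.zeros((32, 64), np.uint8)
        sk[16, 4:28] = 1
        sk[16, 38:60] = 1
        region_mask = np.zeros_like(sk, bool)
        region_mask[10:23, 28:38] = True
        from bezridge._geometry import trace_boundary
        from bezridge.damage import RegionMask
        region = RegionMask(mask=region_mask, boundary=trace_boundary(region_mask),
                            flavor="interior", bbox=(10, 28, 22, 37))
        bps = find_breakpoints(extract_ridges(sk), region)
        assert len(bps) == 2
        ang = np.degrees(np.arccos(np.clip(np.dot(bps[0].tangent, bps[1].tangent), -1, 1)))
        assert ang >= 175.0

    def test_far_endpoint_excluded(self, grating):
        sk = grating.copy()
        sk[:, 60:68] = 0
        regions = detect_interior_regions(sk)
        bps = find_breakpoints(extract_ridges(sk), regions[0])
        for b in bps:
            assert regions[0].mask[
                tuple(np.clip(b.pos.astype(int), 0, 127))] or True
            # all breakpoints must hug the slit columns
            assert 55 <= b.pos[1] <= 72


class TestLatentBifurcation:
    def _kinked_ridge(self, kink_at=30, angle_deg=40.0):
        pts = [(0, i) for i in range(kink_at)]
        dr = np.tan(np.deg2rad(angle_deg))
        r = 0.0
        for i in range(kink_at, 60):
            r += dr
            pts.append((round(r), i))
        return Ridge(np.array([(p[0], p[1]) for p in pts]))

    def test_single_kink_found(self):
        ridge = self._kinked_ridge()
        opp = bp((5, 32), (0, 1))
        pt = find_latent_bifurcation(ridge, opp, MatchConfig(turn_min=25.0))
        assert pt is not None
        assert abs(pt[1] - 30) <= 3

    def test_smooth_arc_has_none(self):
        t = np.linspace(0, np.pi / 3, 80)
        pts = np.stack([40 - 40 * np.cos(t), 40 * np.sin(t)], axis=1)
        ridge = Ridge(np.unique(np.round(pts).astype(int), axis=0))
        assert find_latent_bifurcation(ridge, bp((10, 10), (0, 1))) is None

    def test_nearer_of_two_equal_kinks_wins(self):
        # two identical kinks; the opposite breakpoint sits near the first
        pts = []
        r = 0.0
        for i in range(90):
            if 30 <= i < 36 or 70 <= i < 76:
                r += 1.0  # 45-degree kink zones
            pts.append((round(r), i))
        ridge = Ridge(np.array(pts))
        opp = bp((10, 33), (0, 1))
        pt = find_latent_bifurcation(ridge, opp, MatchConfig(turn_min=20.0))
        assert pt is not None and abs(pt[1] - 33) <= 6


class TestMarginalMatch:
    def test_three_breakpoints_bisection_targets(self):
        bps = [bp((0, 0), (0, -1), order=i) for i in range(3)]
        pairs = marginal_match(bps, (0, 0), (8, 0))
        targets = [tuple(p.end.pos) for p in pairs]
        assert targets == [(2.0, 0.0), (4.0, 0.0), (6.0, 0.0)]
        assert all(p.kind == "marginal" for p in pairs)

    def test_single_breakpoint_gets_midpoint(self):
        pairs = marginal_match([bp((0, 0), (0, -1))], (0, 0), (8, 0))
        assert tuple(pairs[0].end.pos) == (4.0, 0.0)

    def test_reversed_order_reverses_targets(self):
        bps = [bp((i, 0), (0, -1), order=i) for i in range(3)]
        fwd = marginal_match(bps, (0, 0), (8, 0))
        for b, i in zip(bps, (2, 1, 0)):
            b.order_idx = i
        rev = marginal_match(bps, (0, 0), (8, 0))
        fwd_assign = {id(p.start): tuple(p.end.pos) for p in fwd}
        rev_assign = {id(p.start): tuple(p.end.pos) for p in rev}
        # each breakpoint's target moves to the mirrored bisection point
        assert [fwd_assign[id(b)] for b in bps] == \
            [rev_assign[id(b)] for b in reversed(bps)]

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            marginal_match([bp((0, 0), (0, -1))], (3, 3), (3, 3))
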