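"""Restoration-curve generation, the delta metric, and full restoration."""

import numpy as np
import pytest

from bezridge.bezier import BezierSegment, eval_bezier
from bezridge.matching import Breakpoint, MatchPair
from bezridge.metrics import skeleton_recovery
from bezridge.restoration import (RestoreConfig, delta_from_sequences,
                                  delta_score, generate_candidates,
                                  restore_fingerprint,
                                  restore_internal_bifurcation,
                                  restore_latent_bifurcation, restore_region,
                                  _max_curvature, _triangle_controls)
from bezridge.synthgen import (ablate, arc_skeleton, disk_mask,
                               grating_skeleton, y_skeleton)


def bp(pos, neighbor, order=0, side="A"):
    pos = np.asarray(pos, float)
    neighbor = np.asarray(neighbor, float)
    t = neighbor - pos
    return Breakpoint(pos=pos, ridge_id=0, tangent=t / np.linalg.norm(t),
                      neighbor=neighbor, side=side, order_idx=order)


def pair(p1, n1, p2, n2):
    return MatchPair(bp(p1, n1, side="A"), bp(p2, n2, side="B"), 0.0)


class TestGenerateCandidates:
    def test_symmetric_intersection_hand_case(self):
        # tangent lines through P and E meet at Q=(5,-5); half-fraction
        # control points land halfway toward Q
        p = pair((0, 0), (-5, 5), (10, 0), (15, 5))
        cfg = RestoreConfig(fractions=[0.5], rotations=[0.0])
        (cand,) = generate_candidates(p, cfg)
        assert np.allclose(cand.seg.p1, (2.5, -2.5))
        assert np.allclose(cand.seg.p2, (7.5, -2.5))
        assert cand.is_reference

    def test_collinear_fallback_is_straight(self):
        p = pair((0, 0), (0, -5), (0, 12), (0, 17))
        cfg = RestoreConfig(fractions=[0.5], rotations=[0.0])
        (cand,) = generate_candidates(p, cfg)
        samples = eval_bezier(cand.seg, np.linspace(0, 1, 20))
        assert np.allclose(samples[:, 0], 0.0, atol=1e-9)

    def test_default_grid_size(self):
        p = pair((0, 0), (-5, 5), (10, 0), (15, 5))
        cands = generate_candidates(p, RestoreConfig())
        assert len(cands) == 4 * 4 * 5 * 5
        refs = [c for c in cands if c.is_reference]
        assert len(refs) == 1 and refs[0].rot1 == refs[0].rot2 == 0

    def test_reference_has_minimal_curvature_among_unrotated(self):
        p = pair((0, 0), (-5, 5), (10, 0), (15, 5))
        cands = generate_candidates(p, RestoreConfig())
        ref = next(c for c in cands if c.is_reference)
        zero_rot = [c for c in cands if c.rot1 == 0 and c.rot2 == 0]
        assert _max_curvature(ref.seg) <= min(_max_curvature(c.seg)
                                              for c in zero_rot) + 1e-9


class TestDeltaMetric:
    def test_constant_sequences_score_zero(self):
        assert delta_from_sequences([3, 3, 3, 3, 3], [7, 7, 7, 7, 7]) == 0.0

    def test_linear_sequence_hand_value(self):
        # s_i = i, baseline s_1 + (s_5-s_1)*i/5: residuals .8 .6 .4 .2 0
        assert delta_from_sequences([1, 2, 3, 4, 5], [2, 2, 2, 2, 2]) == \
            pytest.approx(2.0, abs=1e-12)

    def test_offset_invariance_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(2, 9)
            s = rng.uniform(0, 20, n)
            d = rng.uniform(0, 20, n)
            c1, c2 = rng.uniform(-50, 50, 2)
            assert delta_from_sequences(s + c1, d + c2) == \
                pytest.approx(delta_from_sequences(s, d), abs=1e-9)

    def test_geometric_equidistant_candidate_scores_zero(self):
        seg = BezierSegment((0, 0), (0, 4), (0, 8), (0, 12))
        prior = [(-3, -5), (-3, 20)]
        subsequent = [(4, -5), (4, 20)]
        assert delta_score(seg, prior, subsequent, n=5) == pytest.approx(0.0, abs=1e-9)

    def test_small_n_rejected(self):
        seg = BezierSegment((0, 0), (1, 1), (2, 2), (3, 3))
        with pytest.raises(ValueError):
            delta_score(seg, [(0, 0)], [(1, 1)], n=1)


class TestRestoreRegion:
    def _region(self, shape=(64, 64)):
        from bezridge._geometry import trace_boundary
        from bezridge.damage import RegionMask
        mask = np.zeros(shape, bool)
        mask[24:40, 24:40] = True
        return RegionMask(mask=mask, boundary=trace_boundary(mask),
                          flavor="interior", bbox=(24, 24, 39, 39))

    def test_straight_flanks_choose_straight_curve(self):
        region = self._region()
        p = pair((32, 24), (32, 20), (32, 40), (32, 44))
        context = [np.array([(24.0, 0.0), (24.0, 63.0)]),
                   np.array([(40.0, 0.0), (40.0, 63.0)])]
        (seg,) = restore_region(region, [p], context)
        samples = eval_bezier(seg, np.linspace(0, 1, 30))
        assert np.abs(samples[:, 0] - 32).max() <= 0.75

    def test_no_context_falls_back_to_reference(self):
        region = self._region()
        p = pair((32, 24), (32, 20), (32, 40), (32, 44))
        (seg,) = restore_region(region, [p], [])
        samples = eval_bezier(seg, np.linspace(0, 1, 30))
        assert np.abs(samples[:, 0] - 32).max() <= 0.75

    def test_zero_pairs_empty(self):
        assert restore_region(self._region(), [], []) == []

    def test_true_arc_beats_most_candidates(self):
        """The delta metric prefers the true (pre-ablation) middle arc over
        at least 90% of generated candidates on a concentric-arc scene."""
        center = (120.0, 60.0)
        radii = (24.0, 32.0, 40.0)
        th = np.linspace(np.pi * 0.75, np.pi * 1.25, 60)

        def arc(radius):
            return np.stack([center[0] + radius * np.sin(th),
                             center[1] + radius * np.cos(th)], axis=1)

        prior, truth, subsequent = arc(radii[0]), arc(radii[1]), arc(radii[2])
        # breakpoints where the middle arc was ablated
        i0, i1 = 20, 40
        p = MatchPair(
            bp(truth[i0], truth[i0 - 4], side="A"),
            bp(truth[i1], truth[i1 + 4], side="B"), 0.0)
        cands = generate_candidates(p, RestoreConfig())
        true_seg = BezierSegment(truth[i0],
                                 truth[i0] + (truth[i1] - truth[i0]) / 3,
                                 truth[i0] + 2 * (truth[i1] - truth[i0]) / 3,
                                 truth[i1])
        # fit the true gap segment properly from the arc samples
        from bezridge.bezier import fit_open_path
        true_seg = fit_open_path(truth[i0:i1 + 1])[0]
        d_true = delta_score(true_seg, prior, subsequent)
        d_all = [delta_score(c, prior, subsequent) for c in cands]
        assert (np.asarray(d_all) >= d_true).mean() >= 0.9


class TestLatentBifurcation:
    def test_collinear_hand_construction(self):
        b2 = bp((9, 0), (12, 0))
        seg = restore_latent_bifurcation((0, 0), b2, fraction=1 / 3)
        assert np.allclose(seg.p0, (0, 0)) and np.allclose(seg.p1, (0, 0))
        assert np.allclose(seg.p2, (6, 0)) and np.allclose(seg.p3, (9, 0))

    def test_curve_passes_through_bifurcation_at_t0(self):
        b2 = bp((20, 14), (24, 16))
        seg = restore_latent_bifurcation((3, 2), b2)
        assert np.allclose(eval_bezier(seg, 0.0), (3, 2))

    def test_end_tangent_parallel_to_ridge_direction(self):
        b2 = bp((20, 14), (24, 16))
        seg = restore_latent_bifurcation((3, 2), b2)
        tangent = seg.p3 - seg.p2  # Bezier end tangent direction
        ridge_dir = np.array([20.0, 14.0]) - np.array([24.0, 16.0])
        cross = tangent[0] * ridge_dir[1] - tangent[1] * ridge_dir[0]
        assert abs(cross) <= 1e-9 * np.linalg.norm(tangent) * np.linalg.norm(ridge_dir)


class TestInternalBifurcation:
    def test_triangle_hand_case(self):
        Ca, Cb = _triangle_controls(np.array([0.0, 2.0]), np.array([0.0, 0.0]))
        got = {tuple(Ca), tuple(Cb)}
        assert got == {(-2.0, 2.0), (2.0, 2.0)}

    @pytest.mark.parametrize("seed", range(20))
    def test_triangle_properties_randomized(self, seed):
        rng = np.random.default_rng(seed)
        E3 = rng.uniform(-50, 50, 2)
        P3 = E3 + rng.uniform(-10, 10, 2)
        if np.allclose(P3, E3):
            P3 = E3 + (1.0, 0.0)
        Ca, Cb = _triangle_controls(E3, P3)
        R = np.linalg.norm(E3 - P3)
        # right angle at P3
        assert abs(np.dot(Ca - P3, Cb - P3)) <= 1e-6 * R * R
        # circumcenter at E3: all vertices at distance R
        for v in (Ca, Cb, P3):
            assert np.linalg.norm(v - E3) == pytest.approx(R, rel=1e-9)
        # isosceles legs
        assert np.linalg.norm(Ca - P3) == pytest.approx(np.linalg.norm(Cb - P3),
                                                        rel=1e-9)

    def test_degenerate_raises(self):
        b1 = bp((0, 10), (0, 14))
        b2 = bp((8, 10), (8, 14))
        b3 = bp((4, 0), (4, 1))
        b3.neighbor = b3.pos.copy()  # P3 == E3: no triangle
        with pytest.raises(ValueError):
            restore_internal_bifurcation(b1, b2, b3)

    def test_mirror_symmetric_estimate_on_axis(self):
        b1 = bp((-6, 12), (-8, 16), side="B")
        b2 = bp((6, 12), (8, 16), side="B")
        b3 = bp((0, 2), (0, -2), side="A")
        _, est = restore_internal_bifurcation(b1, b2, b3)
        assert est[0] == pytest.approx(0.0, abs=1e-9)

    def test_y_fixture_estimate_close_to_truth(self):
        skel, true_bif = y_skeleton((96, 128), 8)
        mask = disk_mask(skel.shape, true_bif, 10)
        _, _, report = restore_fingerprint(ablate(skel, mask))
        assert report["bifurcations"] >= 1


class TestRestoreFingerprint:
    def test_intact_input_unchanged(self, grating):
        _, restored, report = restore_fingerprint(grating)
        assert report["regions"] == 0
        assert np.array_equal(restored, grating)

    def test_two_regions_both_restored(self, grating):
        m1 = disk_mask(grating.shape, (40, 44), 12)
        m2 = disk_mask(grating.shape, (90, 84), 12)
        ab = ablate(grating, m1 | m2)
        _, restored, report = restore_fingerprint(ab)
        assert report["regions"] == 2
        new = restored.astype(bool) & ~ab.astype(bool)
        assert (new & m1).sum() > 0 and (new & m2).sum() > 0

    def test_restored_pixels_stay_local(self, grating):
        mask = disk_mask(grating.shape, (64, 64), 12)
        ab = ablate(grating, mask)
        from bezridge.damage import detect_all
        regions = detect_all(ab)
        _, restored, _ = restore_fingerprint(ab, regions=regions)
        allowed = np.zeros_like(mask)
        from skimage.morphology import dilation
        for r in regions:
            allowed |= dilation(r.mask, np.ones((5, 5), bool))
        new = restored.astype(bool) & ~ab.astype(bool)
        assert not (new & ~allowed).any()

    def test_deterministic(self, arcs):
        mask = disk_mask(arcs.shape, (110, 80), 12)
        ab = ablate(arcs, mask)
        _, r1, _ = restore_fingerprint(ab)
        _, r2, _ = restore_fingerprint(ab)
        assert np.array_equal(r1, r2)

    def test_arc_scene_recovery(self, arcs):
        mask = disk_mask(arcs.shape, (110, 80), 12)
        ab = ablate(arcs, mask)
        _, restored, _ = restore_fingerprint(ab)
        rec, prec = skeleton_recovery(restored, arcs, mask, tol=2.0)
        assert rec >= 0.8 and prec >= 0.8
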