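"""Unit and property tests for the circularity shape loss."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odcseg.nn import Tensor
from odcseg.shape_loss import (DegenerateRegionError, RadialProfile,
                               ShapeLossConfig, centroid, circularity_term,
                               extract_region_contours, radial_profile,
                               shape_loss_hard, shape_loss_soft,
                               shape_loss_total)
from odcseg.synthetic_data import PhantomSpec, generate_phantom, one_hot

from .conftest import circle_points, ellipse_points


def concentric_map(size=128, r_disc=40, r_cup=20, center=None):
    c = center or (size // 2, size // 2)
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(yy - c[0], xx - c[1])
    lm = np.zeros((size, size), dtype=np.uint8)
    lm[r <= r_disc] = 1
    lm[r <= r_cup] = 2
    return lm


class TestContourExtraction:
    def test_square_region_boundary_pixels(self):
        # disc = 5x5 square (class 1) with a 3x3 cup (class 2) inside;
        # boundaries enumerated by brute force as region pixels with a
        # non-region 8-neighbour
        lm = np.zeros((7, 7), dtype=np.uint8)
        lm[1:6, 1:6] = 1
        lm[2:5, 2:5] = 2
        contours = extract_region_contours(lm)

        def brute(mask):
            pts = set()
            for i, j in np.argwhere(mask):
                nb = mask[max(i - 1, 0):i + 2, max(j - 1, 0):j + 2]
                if nb.size < 9 or not nb.all():
                    pts.add((i, j))
            return pts

        assert {tuple(p) for p in contours.disc_points.astype(int)} == brute(lm >= 1)
        assert {tuple(p) for p in contours.cup_points.astype(int)} == brute(lm == 2)
        assert len(contours.disc_points) == 16
        assert len(contours.cup_points) == 8

    def test_single_pixel_cup_is_degenerate(self):
        lm = np.zeros((5, 5), dtype=np.uint8)
        lm[1:4, 1:4] = 1
        lm[2, 2] = 2
        with pytest.raises(DegenerateRegionError):
            extract_region_contours(lm)

    def test_all_background_is_degenerate(self):
        with pytest.raises(DegenerateRegionError):
            extract_region_contours(np.zeros((5, 5), dtype=np.uint8))


class TestCentroidAndProfile:
    def test_centroid_examples(self):
        c = centroid([(0, 0), (0, 2), (2, 0), (2, 2)])
        assert (c.row, c.col) == (1, 1)
        c = centroid([(3, 7)])
        assert (c.row, c.col) == (3, 7)
        c = centroid(circle_points((10, 10), 5))
        assert np.hypot(c.row - 10, c.col - 10) < 1e-9

    def test_centroid_empty_raises(self):
        with pytest.raises(DegenerateRegionError):
            centroid(np.empty((0, 2)))

    def test_radial_profile_circle_and_ellipse(self):
        prof = radial_profile(circle_points((3, -2), 5), centroid(circle_points((3, -2), 5)))
        assert np.allclose(prof.distances, 5)
        assert prof.mean_distance == pytest.approx(5)
        # 4 axis points of an ellipse a=2, b=1
        pts = [(2, 0), (0, 1), (-2, 0), (0, -1)]
        from odcseg.shape_loss import Centroid
        prof = radial_profile(pts, Centroid(0, 0))
        assert sorted(prof.distances) == [1, 1, 2, 2]
        assert prof.mean_distance == pytest.approx(1.5)

    def test_coincident_points_degenerate(self):
        from odcseg.shape_loss import Centroid
        with pytest.raises(DegenerateRegionError):
            radial_profile([(1, 1)] * 5, Centroid(1, 1))


class TestCircularityTerm:
    def test_circle_is_zero(self):
        prof = RadialProfile(distances=np.full(360, 7.3), mean_distance=7.3)
        assert circularity_term(prof) == 0.0

    def test_hand_computed_value(self):
        # distances {2,1,2,1}: mean 1.5, variance 0.25 -> 0.25 / 1.5^2
        prof = RadialProfile(distances=np.array([2.0, 1, 2, 1]), mean_distance=1.5)
        assert circularity_term(prof) == pytest.approx(0.25 / 2.25)

    def test_printed_normalization_mode(self):
        prof = RadialProfile(distances=np.array([2.0, 1, 2, 1]), mean_distance=1.5)
        cfg = ShapeLossConfig(normalization="printed")
        assert circularity_term(prof, cfg) == pytest.approx(4 * 0.25 / 1.5)

    def test_absolute_deviation_mode(self):
        prof = RadialProfile(distances=np.array([2.0, 1, 2, 1]), mean_distance=1.5)
        cfg = ShapeLossConfig(deviation="absolute")
        assert circularity_term(prof, cfg) == pytest.approx(0.5 / 1.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.lists(st.floats(min_value=0.1, max_value=10), min_size=3, max_size=50))
    def test_scale_invariance_property(self, s, distances):
        d = np.asarray(distances)
        p1 = RadialProfile(d, float(d.mean()))
        p2 = RadialProfile(s * d, float(s * d.mean()))
        assert circularity_term(p2) == pytest.approx(circularity_term(p1), rel=1e-9)
        assert circularity_term(p1) >= 0

    def test_ellipse_monotonicity(self):
        values = []
        for ratio in [1.0, 1.25, 1.5, 2.0, 3.0]:
            pts = ellipse_points(ratio, 1.0)
            prof = radial_profile(pts, centroid(pts))
            values.append(circularity_term(prof))
        assert all(b > a for a, b in zip(values, values[1:]))


class TestShapeLossHard:
    def test_rasterized_circles_near_zero(self):
        v = shape_loss_hard(concentric_map()).as_floats()
        assert v.total < 0.01
        assert v.total == v.cup_term + v.disc_term
        assert v.cup_term >= 0 and v.disc_term >= 0

    def test_translation_invariance(self):
        lm = concentric_map(128, 30, 15, center=(60, 60))
        shifted = np.roll(np.roll(lm, 13, axis=0), -7, axis=1)
        v0 = shape_loss_hard(lm).as_floats()
        v1 = shape_loss_hard(shifted).as_floats()
        assert v1.total == pytest.approx(v0.total, abs=1e-12)

    def test_elliptic_disc_dominates_circular_cup(self):
        size = 128
        yy, xx = np.mgrid[0:size, 0:size]
        lm = np.zeros((size, size), dtype=np.uint8)
        lm[(((yy - 64) / 50) ** 2 + ((xx - 64) / 25) ** 2) <= 1] = 1
        lm[np.hypot(yy - 64, xx - 64) <= 15] = 2
        v = shape_loss_hard(lm).as_floats()
        assert v.cup_term < 0.01
        assert v.disc_term > v.cup_term

    def test_degenerate_regions_get_penalty(self):
        v = shape_loss_hard(np.zeros((32, 32), dtype=np.uint8)).as_floats()
        assert v.cup_term == v.disc_term == 10.0
        cfg = ShapeLossConfig(degenerate_penalty=3.5)
        v = shape_loss_hard(np.zeros((32, 32), dtype=np.uint8), cfg).as_floats()
        assert v.total == 7.0


class TestShapeLossSoft:
    def test_one_hot_matches_hard_on_random_phantoms(self):
        rels = []
        for seed in range(50):
            _, lm = generate_phantom(PhantomSpec(
                image_size=64, boundary_jitter=(seed % 4) * 0.03, seed=seed))
            hard = shape_loss_hard(lm).as_floats()
            soft = shape_loss_soft(one_hot(lm)).as_floats()
            rels.append(abs(soft.total - hard.total) / hard.total)
        assert max(rels) < 0.05

    def test_uniform_probabilities_are_degenerate(self):
        v = shape_loss_soft(np.full((3, 32, 32), 1 / 3))
        assert float(v.cup_term) == 10.0
        assert float(v.disc_term) == 10.0

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            shape_loss_soft(np.full((3, 8, 8), 0.9))
        with pytest.raises(ValueError):
            shape_loss_soft(np.full((3, 8, 8), -0.1))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter
        h = w = 20
        logits = gaussian_filter(rng.normal(0, 1, (3, h, w)), (0, 2, 2))
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.hypot(yy - 10, xx - 10)
        logits[2] += 3 * (r < 4)
        logits[1] += 3 * ((r >= 4) & (r < 7))
        logits[0] += 3 * (r >= 7)
        e = np.exp(logits - logits.max(0))
        probs = e / e.sum(0)

        t = Tensor(probs, requires_grad=True)
        shape_loss_soft(t).total.backward()
        grad = t.grad

        def _raw_total(p):
            # evaluate the two region terms directly so perturbed maps need
            # not renormalize to simplex constraints
            from odcseg.shape_loss import DEFAULT_CONFIG, _soft_term
            cup = _soft_term(Tensor(p[2]), DEFAULT_CONFIG)
            disc = _soft_term(Tensor(p[1] + p[2]), DEFAULT_CONFIG)
            return float(cup.data) + float(disc.data)

        eps = 1e-4

        def fd_safe(p, i, j):
            """True when an eps-perturbation of pixel (i, j) cannot flip any
            3x3 min-pool argmin; finite differences straddle a kink of the
            piecewise-smooth loss otherwise (where only a subgradient
            exists), so such probes are skipped."""
            pe = np.pad(p, 1, mode="edge")
            val = p[i, j]
            for ci in range(max(i - 1, 0), min(i + 2, h)):
                for cj in range(max(j - 1, 0), min(j + 2, w)):
                    nb = np.sort(pe[ci:ci + 3, cj:cj + 3].ravel())
                    if val - nb[0] <= 2 * eps and nb[1] - val <= 2 * eps:
                        return False
            return True

        checked = 0
        for c, i, j in zip(rng.integers(0, 3, 200), rng.integers(0, h, 200),
                           rng.integers(0, w, 200)):
            if not (fd_safe(probs[2], i, j)
                    and fd_safe(probs[1] + probs[2], i, j)):
                continue
            p1, p2 = probs.copy(), probs.copy()
            p1[c, i, j] += eps
            p2[c, i, j] -= eps
            fd = (_raw_total(p1) - _raw_total(p2)) / (2 * eps)
            an = grad[c, i, j]
            assert abs(fd - an) / max(abs(fd), abs(an), 1e-8) < 1e-3
            checked += 1
            if checked == 20:
                break
        assert checked == 20


class TestShapeLossTotal:
    def test_additivity_and_commutativity(self):
        _, lm = generate_phantom(PhantomSpec(image_size=64, seed=9))
        oh = one_hot(lm)
        single = float(shape_loss_soft(oh).total)
        total = float(shape_loss_total([oh, oh, oh, oh]))
        assert total == pytest.approx(4 * single, rel=1e-9)
        uniform = np.full((3, 64, 64), 1 / 3)
        maps = [oh, uniform, oh, oh]
        vals = {float(shape_loss_total(perm))
                for perm in (maps, maps[::-1], [maps[1], maps[0], maps[3], maps[2]])}
        assert len(vals) == 1
        assert float(shape_loss_total(maps)) == pytest.approx(3 * single + 20.0, rel=1e-6)

    def test_wrong_count_rejected(self):
        _, lm = generate_phantom(PhantomSpec(image_size=64, seed=9))
        with pytest.raises(ValueError):
            shape_loss_total([one_hot(lm)] * 3)
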