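"""Classical midline detectors: examples, cross-detector oracles,
equivariance and degeneracy handling."""

import numpy as np
import pytest

from glottalmidline.detectors import (
    DETECTORS, Midline, EmptyImageError, DegenerateShapeError,
    LineMissesSupportError, midline_tb, midline_lr, midline_odr,
    midline_pca, midline_moments, midline_ellipse, line_to_endpoints,
    image_moments)
from glottalmidline.benchmark import rasterized_ellipse


def random_weighted_image(rng, shape=(48, 48)):
    """Weighted blob with a random elongated orientation."""
    img = np.zeros(shape)
    n = rng.integers(60, 200)
    ang = rng.uniform(0, np.pi)
    d = np.array([np.cos(ang), np.sin(ang)])
    c = np.array(shape[::-1]) / 2
    pts = c + rng.normal(0, 1, (n, 1)) * d * 15 + rng.normal(0, 2.0, (n, 2))
    pts = np.clip(np.rint(pts).astype(int), 0, np.array(shape[::-1]) - 1)
    for x, y in pts:
        img[y, x] += rng.integers(1, 5)
    return img


def axis_angle(ml: Midline) -> float:
    return ml.angle


class TestTopBottom:
    def test_upright_ellipse_gives_vertical_axis(self):
        mask, gt = rasterized_ellipse(80, 30, 0.0)
        ml = midline_tb(mask)
        assert ml.P[0] == pytest.approx(ml.A[0], abs=0.5)
        assert abs(np.degrees(ml.angle)) == pytest.approx(90.0, abs=0.5)

    def test_multiple_top_pixels_use_center_of_mass(self):
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[1, 3] = mask[1, 5] = 1         # top row: x in {3, 5}
        mask[2:6, 4] = 1
        ml = midline_tb(mask)
        assert ml.P == (4.0, 1.0)

    def test_weighted_row_center_of_mass(self):
        img = np.zeros((6, 6))
        img[1, 2], img[1, 4] = 1.0, 3.0     # weighted mean x = 3.5
        img[2:5, 3] = 1.0
        assert midline_tb(img).P == (pytest.approx(3.5), 1.0)


class TestLinearRegression:
    def test_exact_line_recovered(self):
        img = np.zeros((32, 32))
        ys = np.arange(4, 28)
        xs = 2 + ys                          # pixels exactly on x = 2 + y
        img[ys, xs] = 1
        d = midline_lr(img).direction
        assert d[0] / d[1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_weighted_normal_equations(self):
        rng = np.random.default_rng(2)
        img = random_weighted_image(rng)
        ys, xs = np.nonzero(img)
        w = img[ys, xs]
        # closed-form weighted normal equations for x = t0 + t1 * y
        W = np.sum(w)
        my, mx = np.sum(w * ys) / W, np.sum(w * xs) / W
        t1 = np.sum(w * (ys - my) * (xs - mx)) / np.sum(w * (ys - my) ** 2)
        d = midline_lr(img, largest_component=False).direction
        assert d[0] / d[1] == pytest.approx(t1, abs=1e-9)

    def test_rotated_ellipse_slope_biased_toward_regression_direction(self):
        mask, gt = rasterized_ellipse(80, 30, 45.0)
        lr_ang = abs(np.degrees(midline_lr(mask).angle))
        true_ang = abs(np.degrees(gt.angle))
        pca_ang = abs(np.degrees(midline_pca(mask).angle))
        # transposed regression pulls the axis toward vertical (|angle|
        # further from the true axis than the symmetric estimator)
        assert abs(lr_ang - true_ang) > abs(pca_ang - true_ang)


class TestPrincipalAxisFamily:
    def test_two_point_diagonal(self):
        img = np.zeros((4, 4))
        img[0, 0] = img[2, 2] = 1
        ml = midline_pca(img, largest_component=False)
        assert np.allclose(np.abs(ml.direction), np.sqrt(0.5), atol=1e-9)

    def test_tall_shape_gives_vertical_first_component(self):
        img = np.zeros((32, 32))
        img[4:28, 14:18] = 1
        assert abs(np.degrees(midline_pca(img).angle)) == \
            pytest.approx(90.0, abs=1e-6)

    def test_moments_match_hand_computed_sums(self):
        img = np.zeros((6, 6))
        pix = [(1, 1), (2, 1), (3, 2), (4, 3), (4, 4)]   # (y, x)
        for y, x in pix:
            img[y, x] = 1
        mom = image_moments(img)
        xs = np.array([x for _, x in pix], dtype=float)
        ys = np.array([y for y, _ in pix], dtype=float)
        assert mom["m00"] == pytest.approx(5)
        assert mom["centroid"][0] == pytest.approx(xs.mean())
        assert mom["centroid"][1] == pytest.approx(ys.mean())
        assert mom["mu11"] == pytest.approx(
            np.sum((xs - xs.mean()) * (ys - ys.mean())))
        assert mom["mu20"] == pytest.approx(np.sum((xs - xs.mean()) ** 2))
        assert mom["mu02"] == pytest.approx(np.sum((ys - ys.mean()) ** 2))

    def test_upright_rectangle_has_zero_mu11_and_vertical_axis(self):
        img = np.zeros((20, 20))
        img[2:18, 8:12] = 1
        mom = image_moments(img)
        assert mom["mu11"] == pytest.approx(0.0, abs=1e-9)
        assert abs(np.degrees(midline_moments(img).angle)) == \
            pytest.approx(90.0, abs=1e-9)

    def test_odr_pca_moments_axis_equivalence(self):
        """Total least squares, eigendecomposition and the closed-form
        moment angle are the same principal axis."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            img = random_weighted_image(rng)
            angles = [axis_angle(det(img, largest_component=False)) for det in
                      (midline_odr, midline_pca, midline_moments)]
            spread = max(angles) - min(angles)
            spread = min(spread, np.pi - spread)     # wrap at +-pi/2
            assert spread < 1e-6

    def test_odr_beats_random_perturbations(self):
        rng = np.random.default_rng(3)
        img = random_weighted_image(rng, shape=(32, 32))
        ys, xs = np.nonzero(img)
        w = img[ys, xs]

        def perp_ss(point, direction):
            d = direction / np.linalg.norm(direction)
            r = np.column_stack([xs - point[0], ys - point[1]])
            perp = r[:, 0] * d[1] - r[:, 1] * d[0]
            return np.sum(w * perp ** 2)

        from glottalmidline.detectors import odr_axis

        point, direction = odr_axis(img, largest_component=False)
        best = perp_ss(point, direction)
        ang0 = np.arctan2(direction[1], direction[0])
        for _ in range(10_000):
            ang = ang0 + rng.normal(0, 0.2)
            probe = point + rng.normal(0, 2.0, 2)
            assert best <= perp_ss(
                probe, np.array([np.cos(ang), np.sin(ang)])) + 1e-9


class TestEllipseFit:
    def test_recovers_known_ellipse_parameters(self):
        mask, gt = rasterized_ellipse(80, 30, 20.0)
        ml = midline_ellipse(mask)
        ang_err = abs(np.degrees(ml.angle) - np.degrees(gt.angle))
        assert min(ang_err, 180 - ang_err) < 1.0
        mid = 0.5 * (np.array(ml.P) + np.array(ml.A))
        gt_mid = 0.5 * (np.array(gt.P) + np.array(gt.A))
        assert np.linalg.norm(mid - gt_mid) < 1.5

    def test_circle_is_degenerate(self):
        mask, _ = rasterized_ellipse(40, 40, 0.0)
        with pytest.raises(DegenerateShapeError):
            midline_ellipse(mask)

    def test_tiny_contour_rejected(self):
        img = np.zeros((16, 16))
        img[5, 5] = 1
        with pytest.raises(Exception):
            midline_ellipse(img)


class TestLineToEndpoints:
    def test_vertical_line_through_column(self):
        img = np.zeros((20, 10))
        img[3:17, 4] = 1
        ml = line_to_endpoints(np.array([4.0, 0.0]), np.array([0.0, 1.0]),
                               img)
        # entry/exit land at the pixel-extent boundary (half-pixel
        # beyond the outermost centers at rows 3 and 16)
        assert ml.P[1] == pytest.approx(3.0, abs=0.75)
        assert ml.A[1] == pytest.approx(16.0, abs=0.75)
        assert ml.P[0] == pytest.approx(4.0, abs=0.3)

    def test_hole_in_support_is_ignored(self):
        img = np.zeros((30, 12))
        img[4:26, 5] = 1
        img[12:18, 5] = 0                    # hole in the middle
        ml = line_to_endpoints(np.array([5.0, 0.0]), np.array([0.0, 1.0]),
                               img, largest_component=False)
        assert ml.P[1] == pytest.approx(4.0, abs=0.75)
        assert ml.A[1] == pytest.approx(25.0, abs=0.75)

    def test_endpoints_inside_image(self):
        mask, _ = rasterized_ellipse(120, 40, 10.0, shape=(128, 128))
        ml = midline_pca(mask)
        for pt in (ml.P, ml.A):
            assert 0 <= pt[0] <= 127 and 0 <= pt[1] <= 127

    def test_line_missing_support_rejected(self):
        img = np.zeros((16, 16))
        img[2:5, 2:5] = 1
        with pytest.raises(LineMissesSupportError):
            line_to_endpoints(np.array([14.0, 0.0]), np.array([0.0, 1.0]),
                              img)


@pytest.mark.parametrize("name", sorted(DETECTORS))
def test_empty_image_rejected(name):
    with pytest.raises(EmptyImageError):
        DETECTORS[name](np.zeros((32, 32)))


@pytest.mark.parametrize("name", ["odr", "pca", "moments", "ellipse"])
def test_rotation_equivariance(name):
    det = DETECTORS[name]
    base = axis_angle(det(rasterized_ellipse(80, 30, 0.0)[0]))
    for theta in (-25.0, 10.0, 30.0):
        ang = axis_angle(det(rasterized_ellipse(80, 30, theta)[0]))
        # screen-space rotation by theta turns the measured axis angle
        # (atan2 with y down) by -theta
        shift = np.degrees(base - ang)
        shift = (shift + 90) % 180 - 90
        assert shift == pytest.approx(theta, abs=0.5)


@pytest.mark.parametrize("name", ["odr", "pca", "moments", "ellipse"])
def test_symmetric_masks_recover_true_axis(name):
    from glottalmidline.metrics import miou_midline

    for theta in (-30.0, -10.0, 0.0, 20.0, 30.0):
        mask, gt = rasterized_ellipse(80, 30, theta)
        ml = DETECTORS[name](mask)
        assert miou_midline(mask, gt, ml) >= 0.99


def test_midline_invariants():
    with pytest.raises(ValueError):
        Midline(P=(1.0, 1.0), A=(1.0, 1.0))
    with pytest.raises(ValueError):
        Midline(P=(0.0, 5.0), A=(0.0, 1.0))
    ml = Midline(P=(0.0, 0.0), A=(3.0, 4.0))
    assert np.linalg.norm(ml.direction) == pytest.approx(1.0)
    m, b = Midline(P=(0.0, 1.0), A=(2.0, 5.0)).slope_intercept()
    assert (m, b) == (pytest.approx(2.0), pytest.approx(1.0))
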