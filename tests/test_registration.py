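"""Control-point transform estimation, warping, ROI transfer and mirroring."""

import math

import numpy as np
import pytest

from ivimfusion.registration import (
    ControlPointSet,
    EmptyMaskError,
    PlanarTransform,
    ROIMask,
    SingularConfigurationError,
    downsample_mask,
    estimate_transform,
    mirror_roi,
    target_registration_error,
    transfer_roi,
    warp_image,
)
from ivimfusion.synthetic import PhantomSpec, phantom_masks


def random_points(n, seed, lo=10, hi=240):
    return np.random.default_rng(seed).uniform(lo, hi, (n, 2))


def affine_of(angle_deg=10.0, scale=1.1, t=(5.0, -3.0)):
    th = math.radians(angle_deg)
    m = scale * np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return PlanarTransform("affine", np.column_stack([np.asarray(t, float), m]))


class TestEstimate:
    def test_identity_points_give_identity_transform(self):
        pts = random_points(6, 0)
        tf = estimate_transform(ControlPointSet(pts, pts), "polynomial-2")
        expect = np.zeros((2, 6))
        expect[0, 1] = expect[1, 2] = 1.0
        assert np.allclose(tf.coefficients, expect, atol=1e-9)
        assert np.allclose(tf.residuals, 0, atol=1e-9)

    @pytest.mark.parametrize("family,n", [("affine", 8), ("affine", 3),
                                          ("polynomial-2", 8), ("polynomial-2", 6)])
    def test_generate_and_recover(self, family, n):
        """Exact control points from a known member of the family are
        recovered to coefficient error < 1e-9 with held-out TRE < 1e-6 px."""
        if family == "affine":
            true = affine_of()
        else:
            coef = np.array(
                [[5.0, 1.05, -0.17, 1e-5, -2e-5, 1e-5],
                 [-3.0, 0.17, 1.05, -1e-5, 1e-5, 2e-5]]
            )
            true = PlanarTransform("polynomial-2", coef)
        mov = random_points(n, 1)
        tf = estimate_transform(ControlPointSet(mov, true(mov)), family)
        assert np.allclose(tf.coefficients, true.coefficients, atol=1e-9)
        held = random_points(50, 2)
        assert target_registration_error(tf, held, true(held)) < 1e-6

    def test_family_autoselect_by_point_count(self):
        pts5 = random_points(5, 3)
        assert estimate_transform(ControlPointSet(pts5, pts5)).family == "affine"
        pts6 = random_points(6, 3)
        assert estimate_transform(ControlPointSet(pts6, pts6)).family == "polynomial-2"

    def test_five_points_cannot_fit_polynomial(self):
        pts = random_points(5, 4)
        with pytest.raises(ValueError, match="at least 6"):
            estimate_transform(ControlPointSet(pts, pts), "polynomial-2")

    def test_collinear_points_raise_singular_configuration(self):
        x = np.linspace(0, 100, 6)
        mov = np.column_stack([x, 2 * x + 1])
        with pytest.raises(SingularConfigurationError, match="collinear"):
            estimate_transform(ControlPointSet(mov, mov), "affine")

    def test_points_on_conic_raise_for_polynomial(self):
        th = np.linspace(0, 2 * np.pi, 7)[:-1]
        mov = np.column_stack([50 + 30 * np.cos(th), 50 + 30 * np.sin(th)])
        with pytest.raises(SingularConfigurationError, match="conic"):
            estimate_transform(ControlPointSet(mov, mov), "polynomial-2")

    def test_duplicate_moving_points_rejected(self):
        pts = np.array([[0, 0], [0, 0], [1, 1], [2, 0]], float)
        with pytest.raises(ValueError, match="duplicated"):
            ControlPointSet(pts, pts)


class TestWarp:
    def test_identity_exact_on_grid(self):
        img = np.random.default_rng(0).uniform(0, 1, (32, 32))
        tf = PlanarTransform("affine", np.array([[0.0, 1, 0], [0, 0, 1.0]]))
        assert np.allclose(warp_image(img, tf, img.shape), img, atol=1e-12)

    def test_integer_translation_shifts_exactly(self):
        img = np.random.default_rng(1).uniform(0, 1, (40, 40))
        tf = PlanarTransform("affine", np.array([[3.0, 1, 0], [2.0, 0, 1.0]]))
        out = warp_image(img, tf, img.shape)
        # fixed pixel (y, x) shows moving pixel (y-2, x-3)
        assert np.allclose(out[2:, 3:], img[:-2, :-3], atol=1e-12)
        assert np.allclose(out[:2, :], 0)

    def test_affine_round_trip_recovers_checkerboard(self):
        """Warp by a known affine then by its inverse; the interior must
        come back within 2% mean absolute error of the dynamic range."""
        tiles = np.indices((8, 8)).sum(axis=0) % 2
        img = np.kron(tiles, np.ones((48, 48)))
        tf = affine_of(angle_deg=3.0, scale=1.02, t=(2.3, -1.7))
        fwd = warp_image(img, tf, img.shape)
        back = warp_image(fwd, tf.inverse(), img.shape)
        interior = (slice(48, -48),) * 2
        mae = np.abs(back[interior] - img[interior]).mean()
        assert mae < 0.02

    def test_noninvertible_mapping_warns_but_returns(self):
        coef = np.zeros((2, 6))
        coef[0, 1] = coef[1, 2] = 1.0
        coef[0, 3] = -0.02  # strong fold within the domain
        tf = PlanarTransform("polynomial-2", coef)
        img = np.ones((64, 64))
        with pytest.warns(RuntimeWarning, match="invertible"):
            out = warp_image(img, tf, img.shape)
        assert out.shape == img.shape


class TestTransferROI:
    def test_identity_same_grid(self):
        data = np.zeros((32, 32), bool)
        data[10:20, 8:15] = True
        tf = PlanarTransform("affine", np.array([[0.0, 1, 0], [0, 0, 1.0]]))
        out = transfer_roi(ROIMask(data), tf, (32, 32))
        assert np.array_equal(out.data, data)

    def test_uniform_scaling_quadruples_area(self):
        """2x scaling moving->fixed: the transferred mask area matches the
        Jacobian prediction (4x) within 5%."""
        data = np.zeros((64, 64), bool)
        yy, xx = np.indices(data.shape)
        data |= (xx - 30) ** 2 + (yy - 30) ** 2 <= 12**2
        tf = PlanarTransform("affine", np.array([[0.0, 2, 0], [0, 0, 2.0]]))
        out = transfer_roi(ROIMask(data), tf, (128, 128))
        ratio = out.area_px / data.sum()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_mask_outside_fov_errors(self):
        data = np.zeros((32, 32), bool)
        data[2:6, 2:6] = True
        tf = PlanarTransform("affine", np.array([[500.0, 1, 0], [500.0, 0, 1.0]]))
        with pytest.raises(EmptyMaskError, match="outside"):
            transfer_roi(ROIMask(data), tf, (32, 32))

    def test_empty_source_errors(self):
        tf = PlanarTransform("affine", np.array([[0.0, 1, 0], [0, 0, 1.0]]))
        with pytest.raises(EmptyMaskError):
            transfer_roi(ROIMask(np.zeros((8, 8), bool)), tf, (8, 8))


def brute_force_downsample(fine, p_fine, shape_c, p_coarse, threshold=0.5):
    """Independent per-pixel coverage computation: integrate the fine mask
    over each coarse footprint by explicit 1-D interval overlaps."""
    ny_c, nx_c = shape_c
    out = np.zeros(shape_c, bool)
    ny_f, nx_f = fine.shape
    for i in range(ny_c):
        for j in range(nx_c):
            cov = 0.0
            for fi in range(ny_f):
                oy = min((i + 1) * p_coarse, (fi + 1) * p_fine) - max(i * p_coarse, fi * p_fine)
                if oy <= 0:
                    continue
                for fj in range(nx_f):
                    ox = min((j + 1) * p_coarse, (fj + 1) * p_fine) - max(j * p_coarse, fj * p_fine)
                    if ox > 0 and fine[fi, fj]:
                        cov += ox * oy
            out[i, j] = cov / p_coarse**2 >= threshold
    return out


class TestDownsample:
    def test_full_mask_stays_full(self):
        m = ROIMask(np.ones((64, 64), bool), pixel_size=1.0)
        out = downsample_mask(m, (16, 16), 4.0)
        assert out.data.all()

    def test_aligned_block_maps_to_single_pixel(self):
        data = np.zeros((16, 16), bool)
        data[4:8, 8:12] = True  # one 4x4 block == coarse pixel (1, 2)
        out = downsample_mask(ROIMask(data, pixel_size=1.0), (4, 4), 4.0)
        expect = np.zeros((4, 4), bool)
        expect[1, 2] = True
        assert np.array_equal(out.data, expect)

    def test_matches_exhaustive_coverage_oracle(self):
        """Majority-rule downsampling equals the brute-force coverage
        computation on random masks, for aligned and non-integer ratios."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            fine = rng.uniform(size=(24, 24)) < 0.4
            if trial % 2:
                p_f, p_c, shape_c = 1.0, 4.0, (6, 6)
            else:
                p_f, p_c, shape_c = 0.75, 3.05, (6, 6)
            expect = brute_force_downsample(fine, p_f, shape_c, p_c)
            m = ROIMask(fine, pixel_size=p_f)
            if not expect.any():
                with pytest.raises(EmptyMaskError):
                    downsample_mask(m, shape_c, p_c)
                continue
            out = downsample_mask(m, shape_c, p_c)
            assert np.array_equal(out.data, expect)

    def test_vanishing_roi_suggests_larger(self):
        data = np.zeros((64, 64), bool)
        data[10, 10] = True
        with pytest.raises(EmptyMaskError, match="larger ROI"):
            downsample_mask(ROIMask(data, pixel_size=1.0), (16, 16), 4.0)

    def test_transfer_then_downsample_identity_idempotent(self):
        data = np.zeros((32, 32), bool)
        data[5:20, 6:18] = True
        tf = PlanarTransform("affine", np.array([[0.0, 1, 0], [0, 0, 1.0]]))
        moved = transfer_roi(ROIMask(data, pixel_size=2.0), tf, (32, 32))
        down = downsample_mask(moved, (32, 32), 2.0)
        assert np.array_equal(down.data, data)


class TestMirror:
    def test_lesion_on_midline_overlaps(self):
        data = np.zeros((64, 64), bool)
        data[30:34, 30:34] = True  # centered on midline x=32
        with pytest.raises(ValueError, match="midline"):
            mirror_roi(ROIMask(data, label="lesion"), 32.0)

    def test_symmetric_phantom_mirror_equal_area_in_zone(self):
        spec = PhantomSpec()
        masks = phantom_masks(spec)
        lesion = ROIMask(masks["lesion"], pixel_size=3.05, label="lesion", zone="pz")
        contra = mirror_roi(lesion, spec.midline_x, masks["pz"])
        assert contra.area_px == lesion.area_px  # left-right symmetric phantom
        assert not np.any(contra.data & lesion.data)
        assert np.all(masks["pz"][contra.data])

    def test_zone_label_preserved(self):
        data = np.zeros((64, 64), bool)
        data[28:31, 24:28] = True
        lesion = ROIMask(data, label="lesion", zone="tz")
        spec = PhantomSpec()
        contra = mirror_roi(lesion, 32.0, phantom_masks(spec)["tz"])
        assert contra.zone == "tz"
        assert contra.label == "contralateral_normal"


class TestTRE:
    def test_exact_points_zero_error(self):
        tf = affine_of()
        pts = random_points(10, 5)
        assert target_registration_error(tf, pts, tf(pts)) == 0.0

    def test_isotropic_jitter_rmse_sqrt2(self):
        """sigma=1 px jitter on both coordinates of 100 held-out points
        gives RMSE ~ sigma*sqrt(2) within 20%."""
        tf = affine_of()
        pts = random_points(100, 6)
        rng = np.random.default_rng(7)
        fixed = tf(pts) + rng.normal(0, 1.0, (100, 2))
        tre = target_registration_error(tf, pts, fixed)
        assert tre == pytest.approx(np.sqrt(2), rel=0.20)

    def test_single_point_equals_distance(self):
        tf = PlanarTransform("affine", np.array([[0.0, 1, 0], [0, 0, 1.0]]))
        tre = target_registration_error(tf, [[0, 0]], [[3.0, 4.0]])
        assert tre == pytest.approx(5.0)

    def test_pixel_size_converts_to_mm(self):
        tf = PlanarTransform("affine", np.array([[0.0, 1, 0], [0, 0, 1.0]]))
        tre = target_registration_error(tf, [[0, 0]], [[3.0, 4.0]], pixel_size_mm=0.5)
        assert tre == pytest.approx(2.5)
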