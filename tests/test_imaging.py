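"""Stack I/O, equatorial projection, orientation, ROIs, normalization."""

import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from blastoquant.imaging import (
    ROI,
    Projection,
    ZStack,
    derive_rois,
    equatorial_projection,
    load_stack,
    mask_orientation_deg,
    normalize_intensity,
    orient_long_axis,
    rotate_mask,
    write_stack,
)
from blastoquant.simulate import ImageSimParams, generate_embryo_stack

from conftest import small_image_params


def _toy_stack(rng, n_slices=12, shape=(20, 20)):
    voxels = rng.uniform(0, 100, size=(2, n_slices, *shape))
    return ZStack(
        voxels=voxels,
        channel_names=["FISH", "DAPI"],
        pixel_size_um=0.18,
        slice_interval_um=0.22,
    )


class TestStackIO:
    def test_round_trip_identity(self, rng, tmp_path):
        stack = _toy_stack(rng)
        stack.voxels = stack.voxels.astype(np.float32)
        path = write_stack(stack, tmp_path / "s.tif")
        back = load_stack(path)
        np.testing.assert_array_equal(back.voxels, stack.voxels)
        assert back.channel_names == ["FISH", "DAPI"]

    def test_slice_interval_metadata_survives(self, rng, tmp_path):
        stack = _toy_stack(rng)
        stack.slice_interval_um = 0.22
        back = load_stack(write_stack(stack, tmp_path / "s.tif"))
        assert back.slice_interval_um == 0.22
        assert back.pixel_size_um == 0.18

    def test_missing_sidecar_field_named(self, rng, tmp_path):
        import yaml

        stack = _toy_stack(rng)
        path = write_stack(stack, tmp_path / "s.tif")
        side = path.with_suffix(".tif.yaml")
        meta = yaml.safe_load(side.read_text())
        del meta["slice_interval_um"]
        side.write_text(yaml.safe_dump(meta))
        with pytest.raises(ValueError, match="slice_interval_um"):
            load_stack(path)

    def test_truncated_file_no_partial_object(self, rng, tmp_path):
        stack = _toy_stack(rng)
        path = write_stack(stack, tmp_path / "s.tif")
        raw = path.read_bytes()
        path.write_bytes(raw[: len(raw) // 3])
        with pytest.raises(ValueError, match="could not parse"):
            load_stack(path)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ZStack(
                voxels=-np.ones((1, 2, 4, 4)),
                channel_names=["FISH"],
                pixel_size_um=0.18,
                slice_interval_um=0.22,
            )


class TestEquatorialProjection:
    def test_span_bookkeeping(self, rng):
        stack = _toy_stack(rng)
        stack.slice_interval_um = 0.222
        proj = equatorial_projection(stack, "FISH", n_slices=10)
        assert proj.span_um == pytest.approx(2.22)
        assert proj.n_source_slices == 10

    def test_constant_stack_projects_to_constant(self):
        stack = ZStack(
            voxels=np.full((1, 12, 8, 8), 7.0),
            channel_names=["FISH"],
            pixel_size_um=0.18,
            slice_interval_um=0.22,
        )
        proj = equatorial_projection(stack, "FISH", n_slices=10)
        np.testing.assert_array_equal(proj.pixels, np.full((8, 8), 7.0))

    def test_matches_brute_force_max_oracle(self, rng):
        """Element-wise max over the window vs an independent triple loop."""
        vox = rng.uniform(0, 1, size=(1, 4, 4, 4))
        stack = ZStack(vox, ["FISH"], 0.18, 0.22)
        proj = equatorial_projection(stack, "FISH", n_slices=4)
        lo, hi = proj.source_slices
        expected = np.zeros((4, 4))
        for r in range(4):
            for c in range(4):
                m = -np.inf
                for z in range(lo, hi):
                    m = max(m, vox[0, z, r, c])
                expected[r, c] = m
        np.testing.assert_allclose(proj.pixels, expected)

    def test_too_few_slices_errors(self, rng):
        stack = _toy_stack(rng, n_slices=5)
        with pytest.raises(ValueError, match="fewer"):
            equatorial_projection(stack, "FISH", n_slices=10)

    def test_window_centred_on_largest_cross_section(self):
        """The 10-slice window must straddle the slice where the specimen's
        cross-sectional area peaks (the equator of the spherical cell)."""
        stack, truth = generate_embryo_stack(small_image_params(n_slices=21, seed=4))
        proj = equatorial_projection(stack, "FISH", n_slices=10)
        areas = truth.cell_masks[0].sum(axis=(1, 2))
        eq = int(np.argmax(areas))
        lo, hi = proj.source_slices
        assert lo <= eq < hi

    def test_mip_idempotent_on_single_slice(self, rng):
        single = ZStack(rng.uniform(0, 1, (1, 1, 6, 6)), ["FISH"], 0.18, 0.22)
        proj = equatorial_projection(single, "FISH", n_slices=1)
        np.testing.assert_array_equal(proj.pixels, single.voxels[0, 0])


def _ellipse_mask(angle_from_y_deg, shape=(200, 200), a=60, b=25):
    mask = np.zeros(shape, bool)
    rr, cc = draw_ellipse(
        shape[0] // 2, shape[1] // 2, a, b, rotation=np.deg2rad(-angle_from_y_deg)
    )
    mask[rr, cc] = True
    return mask


class TestOrientation:
    def test_already_aligned_is_identity(self):
        mask = _ellipse_mask(0.0)
        proj = Projection(mask * 5.0, (0, 1), 0.22)
        _, angle = orient_long_axis(proj, ROI(mask=mask, kind="whole_embryo"))
        assert abs(angle) <= 0.5

    @pytest.mark.parametrize("true_angle", [-60.0, -30.0, 10.0, 30.0, 75.0])
    def test_detected_angle_matches_moment_oracle(self, true_angle):
        """Angle from second central moments; post-rotation axis y-parallel."""
        mask = _ellipse_mask(true_angle)
        # independent oracle: eigenvector of the second-central-moment matrix
        ys, xs = np.nonzero(mask)
        cov = np.cov(np.stack([xs, ys]))
        evals, evecs = np.linalg.eigh(cov)
        major = evecs[:, np.argmax(evals)]
        oracle = np.degrees(np.arctan2(major[0], major[1]))  # from y-axis
        if oracle <= -90:
            oracle += 180
        elif oracle > 90:
            oracle -= 180
        detected = mask_orientation_deg(mask)
        assert abs(detected) == pytest.approx(abs(oracle), abs=1.0)
        assert abs(abs(detected) - abs(true_angle)) <= 1.0
        proj = Projection(mask * 5.0, (0, 1), 0.22)
        rotated, angle = orient_long_axis(proj, ROI(mask=mask, kind="whole_embryo"))
        residual = mask_orientation_deg(rotate_mask(mask, angle))
        assert abs(residual) <= 1.0
        assert rotated.oriented

    def test_orientation_involution(self):
        mask = _ellipse_mask(30.0)
        proj = Projection(mask * 5.0, (0, 1), 0.22)
        rotated, angle = orient_long_axis(proj, ROI(mask=mask, kind="whole_embryo"))
        mask2 = rotate_mask(mask, angle)
        _, angle2 = orient_long_axis(rotated, ROI(mask=mask2, kind="whole_embryo"))
        assert abs(angle2) <= 0.5

    def test_intensity_nearly_conserved(self, rng):
        mask = _ellipse_mask(30.0)
        img = np.where(mask, rng.uniform(1, 2, mask.shape), 0.0)
        proj = Projection(img, (0, 1), 0.22)
        rotated, _ = orient_long_axis(proj, ROI(mask=mask, kind="whole_embryo"))
        assert rotated.pixels.sum() == pytest.approx(img.sum(), rel=0.01)

    def test_degenerate_circular_mask_warns_angle_zero(self):
        yy, xx = np.ogrid[:100, :100]
        mask = (yy - 50) ** 2 + (xx - 50) ** 2 <= 30**2
        proj = Projection(mask * 1.0, (0, 1), 0.22)
        with pytest.warns(UserWarning, match="circular"):
            _, angle = orient_long_axis(proj, ROI(mask=mask, kind="whole_embryo"))
        assert angle == 0.0


class TestDeriveRois:
    def test_ground_truth_pass_through_iou_one(self):
        stack, truth = generate_embryo_stack(small_image_params(seed=1))
        proj = equatorial_projection(stack, "FISH", 10)
        gt = truth.roi_masks(proj.source_slices)
        rois = derive_rois(proj, mode="ground_truth", geometry="oocyte", ground_truth_masks=gt)
        assert len(rois) == 1
        inter = (rois[0].mask & gt[0]).sum()
        union = (rois[0].mask | gt[0]).sum()
        assert inter / union == 1.0

    def test_segment_two_cell_components_and_areas(self):
        """Noiseless touching blastomeres: watershed yields exactly two
        components whose areas match the generator masks within 5%."""
        params = small_image_params(
            image_shape=(160, 320),
            geometry="two_cell",
            blastomere_radii_px=(60.0, 60.0),
            n_spots=1200,
            distribution="uniform",
            poisson_noise=False,
            read_noise_sd=0.0,
            background_level=0.0,
            seed=5,
        )
        stack, truth = generate_embryo_stack(params)
        proj = equatorial_projection(stack, "FISH", 10)
        dapi = equatorial_projection(stack, "DAPI", 10)
        rois = derive_rois(proj, dapi, mode="segment", geometry="two_cell")
        assert len(rois) == 2
        gt = truth.roi_masks(proj.source_slices)
        for roi, gt_mask in zip(rois, gt):
            assert roi.area_px == pytest.approx(gt_mask.sum(), rel=0.05)

    def test_segment_rois_disjoint_and_inside_foreground(self):
        params = small_image_params(
            image_shape=(128, 192),
            geometry="two_cell",
            blastomere_radii_px=(30.0, 30.0),
            n_spots=400,
            seed=6,
        )
        stack, _ = generate_embryo_stack(params)
        proj = equatorial_projection(stack, "FISH", 10)
        dapi = equatorial_projection(stack, "DAPI", 10)
        a, b = derive_rois(proj, dapi, mode="segment", geometry="two_cell")
        assert not (a.mask & b.mask).any()

    def test_circle_fit_covers_ground_truth(self):
        stack, truth = generate_embryo_stack(small_image_params(seed=2))
        proj = equatorial_projection(stack, "FISH", 10)
        dapi = equatorial_projection(stack, "DAPI", 10)
        [roi] = derive_rois(proj, dapi, mode="circle_fit", geometry="oocyte")
        gt = truth.roi_masks(proj.source_slices)[0]
        assert (roi.mask & gt).sum() / gt.sum() >= 0.99
        assert roi.shape_spec[0] == "circle"

    def test_zero_foreground_errors(self):
        proj = Projection(np.zeros((32, 32)), (0, 1), 0.22)
        with pytest.raises(ValueError):
            derive_rois(proj, mode="segment", geometry="oocyte")


class TestNormalization:
    def test_identical_inputs_identical_outputs(self, rng):
        img = rng.uniform(0, 50, (16, 16))
        p1 = Projection(img.copy(), (0, 1), 0.22)
        p2 = Projection(img.copy(), (0, 1), 0.22)
        n1, n2 = normalize_intensity([p1, p2])
        np.testing.assert_array_equal(n1.pixels, n2.pixels)
        assert n1.normalization == n2.normalization

    def test_constant_batch_maps_to_zero_with_warning(self, constant_projection):
        with pytest.warns(UserWarning, match="degenerate"):
            [out] = normalize_intensity([constant_projection])
        assert (out.pixels == 0).all()

    def test_percentile_normalization_scale_invariant(self, rng):
        imgs = [rng.uniform(0, 50, (16, 16)) for _ in range(3)]
        batch1 = [Projection(i.copy(), (0, 1), 0.22) for i in imgs]
        batch2 = [Projection(2 * i, (0, 1), 0.22) for i in imgs]
        out1 = normalize_intensity(batch1)
        out2 = normalize_intensity(batch2)
        for a, b in zip(out1, out2):
            np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-12)

    def test_explicit_bad_bounds_error(self, constant_projection):
        with pytest.raises(ValueError, match="low"):
            normalize_intensity([constant_projection], bounds=(5.0, 5.0))

    def test_shared_window_applied_to_all(self, rng):
        bright = Projection(rng.uniform(50, 100, (8, 8)), (0, 1), 0.22)
        dim = Projection(rng.uniform(0, 10, (8, 8)), (0, 1), 0.22)
        nb, nd = normalize_intensity([bright, dim])
        assert nb.normalization == nd.normalization
        assert nd.pixels.max() < nb.pixels.max()
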