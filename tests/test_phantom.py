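import numpy as np
import pytest

from petcompare import (
    CordSpec,
    ImageGrid,
    Lesion,
    PhantomSpec,
    VolumetricImage,
    build_activity_truth,
    default_injection,
    make_reconstruction_pair,
    simulate_reconstruction,
    to_suv,
    suv_max,
)
from petcompare.phantom import single_lesion_spec, table5_fixture


def _bare_spec(lesions, background=0.0, cord=None, fov=(80.0, 80.0, 80.0), **kw):
    return PhantomSpec(
        fov_mm=fov,
        lesions=lesions,
        background_activity=background,
        cord=cord,
        injection=default_injection(),
        **kw,
    )


class TestSpecValidation:
    def test_overlapping_lesions_named(self):
        lesions = (
            Lesion((30, 40, 40), 20.0, 1.0),
            Lesion((40, 40, 40), 20.0, 1.0),
        )
        with pytest.raises(ValueError, match="0 and 1"):
            _bare_spec(lesions)

    def test_lesion_outside_fov_rejected(self):
        with pytest.raises(ValueError, match="FOV"):
            _bare_spec((Lesion((5, 40, 40), 20.0, 1.0),))

    def test_truth_spacing_must_be_finer_than_recons(self):
        from petcompare import ReconSpec

        with pytest.raises(ValueError, match="finer"):
            _bare_spec(
                (Lesion((40, 40, 40), 10.0, 1.0),),
                recon_specs=(
                    ReconSpec(7.5, (0.9, 4.1, 5.0)),
                    ReconSpec(4.3, (2.0, 2.0, 5.0)),
                ),
            )


class TestActivityTruth:
    def test_empty_phantom_is_all_zero(self):
        spec = _bare_spec((), background=0.0)
        assert not build_activity_truth(spec).values.any()

    def test_sphere_total_activity_within_2_percent(self):
        # 20 mm sphere at activity a over zero background on the 1 mm grid
        spec = _bare_spec((Lesion((40, 40, 40), 20.0, 5.0),))
        truth = build_activity_truth(spec)
        total = truth.values.sum() * truth.grid.voxel_volume_cm3
        analytic = 5.0 * 4.0 / 3.0 * np.pi * 1.0**3  # radius 1 cm
        assert total == pytest.approx(analytic, rel=0.02)

    def test_cord_voxels_exactly_at_cord_activity(self):
        cord = CordSpec((20.0, 40.0), 5.0, 0.7, z_range_mm=(20.0, 60.0))
        spec = _bare_spec((), background=0.3, cord=cord)
        truth = build_activity_truth(spec)
        from petcompare.phantom import _cylinder_occupancy

        occ = _cylinder_occupancy(truth.grid, cord, spec.fov_mm[2])
        assert np.all(truth.values[occ] == 0.7)


class TestSimulateReconstruction:
    def test_constant_field_stays_constant(self):
        g = ImageGrid((40, 40, 40), (1, 1, 1))
        u = VolumetricImage(g, np.full(g.size, 3.7), "activity")
        out = simulate_reconstruction(u, 6.0, ImageGrid((9, 9, 8), (4.1, 4.1, 5.0)))
        assert np.allclose(out.values, 3.7, atol=1e-12)

    def test_sharper_psf_keeps_higher_peak(self):
        spec = _bare_spec((Lesion((40, 40, 40), 10.0, 5.0),), background=0.1)
        truth = build_activity_truth(spec)
        grid = ImageGrid((40, 40, 16), (2.0, 2.0, 5.0))
        sharp = simulate_reconstruction(truth, 4.3, grid)
        blurry = simulate_reconstruction(truth, 7.5, grid)
        assert sharp.values.max() > blurry.values.max()

    def test_activity_conserved_under_blur_and_resample(self):
        """Normalized convolution + box-mean resampling preserve total
        activity within 0.5% when sources sit >= 3 FWHM from the FOV edge."""
        spec = single_lesion_spec(20.0)
        truth = build_activity_truth(spec)
        total_truth = truth.values.sum() * truth.grid.voxel_volume_cm3
        for rs in spec.recon_specs:
            out = simulate_reconstruction(truth, rs.psf_fwhm_mm, spec.recon_grid(rs))
            total = out.values.sum() * out.grid.voxel_volume_cm3
            assert abs(total - total_truth) / total_truth < 0.005

    def test_under_resolved_psf_warns(self):
        g = ImageGrid((20, 20, 20), (1, 1, 1))
        u = VolumetricImage(g, np.ones(g.size), "activity")
        with pytest.warns(UserWarning, match="under-resolved"):
            simulate_reconstruction(u, 0.5, ImageGrid((5, 5, 5), (4.0, 4.0, 4.0)))

    def test_finer_target_than_truth_rejected(self):
        g = ImageGrid((20, 20, 20), (2, 2, 2))
        u = VolumetricImage(g, np.ones(g.size), "activity")
        with pytest.raises(ValueError, match="coarser"):
            simulate_reconstruction(u, 6.0, ImageGrid((40, 40, 40), (1, 1, 1)))


class TestReconstructionPair:
    def test_same_spec_same_seed_bit_identical(self):
        spec = single_lesion_spec(16.0, noise_sd=0.1, seed=42)
        p1 = make_reconstruction_pair(spec)
        p2 = make_reconstruction_pair(spec)
        for a, b in zip(p1.recons, p2.recons):
            assert np.array_equal(a.values, b.values)

    def test_noise_streams_are_independent(self):
        # two identical reconstruction protocols differ only through their
        # per-reconstruction noise sub-streams
        from petcompare import ReconSpec

        base = single_lesion_spec(16.0)
        same = (
            ReconSpec(7.5, (4.1, 4.1, 5.0), 0.1, "first"),
            ReconSpec(7.5, (4.1, 4.1, 5.0), 0.1, "second"),
        )
        spec = PhantomSpec(
            fov_mm=base.fov_mm,
            lesions=base.lesions,
            background_activity=base.background_activity,
            cord=base.cord,
            recon_specs=same,
            injection=base.injection,
            seed=42,
        )
        pair = make_reconstruction_pair(spec)
        assert not np.array_equal(pair.recons[0].values, pair.recons[1].values)

    def test_partial_volume_ordering_for_small_lesion(self):
        """A 10 mm sphere keeps a strictly higher peak on the sharper
        reconstruction (noiseless)."""
        spec = single_lesion_spec(10.0)
        pair = make_reconstruction_pair(spec)
        suvs = [to_suv(img, spec.injection) for img in pair.recons]
        peak_blurry = suv_max(suvs[0], pair.masks[0].lesions[0])
        peak_sharp = suv_max(suvs[1], pair.masks[1].lesions[0])
        assert peak_sharp > peak_blurry

    def test_lesion_mask_rasterization(self):
        """Centre-in rasterization matches a brute-force oracle exactly, and
        the volume error obeys the surface-layer bound (half target spacing
        per face, i.e. spacing x cross-section per axis)."""
        spec = single_lesion_spec(24.0)
        pair = make_reconstruction_pair(spec)
        les = spec.lesions[0]
        for gm in pair.masks:
            mask = gm.lesions[0]
            g = mask.grid
            centers = [g.axis_centers(a) for a in range(3)]
            d2 = (
                (centers[0][:, None, None] - les.center_mm[0]) ** 2
                + (centers[1][None, :, None] - les.center_mm[1]) ** 2
                + (centers[2][None, None, :] - les.center_mm[2]) ** 2
            )
            assert np.array_equal(mask.occupancy, d2 <= les.radius_mm**2)
            analytic = 4 / 3 * np.pi * (les.radius_mm / 10) ** 3  # cm^3
            area = np.pi * (les.radius_mm / 10) ** 2  # max cross-section, cm^2
            bound = sum(s / 10 * area for s in g.spacing)
            assert abs(mask.volume_cm3 - analytic) <= bound

    def test_masks_exist_on_both_grids(self):
        spec = single_lesion_spec(16.0)
        pair = make_reconstruction_pair(spec)
        for gm, img in zip(pair.masks, pair.recons):
            assert gm.cord is not None and not gm.cord.is_empty()
            assert gm.lesions[0].grid.approx_equal(img.grid)
            assert np.all(~gm.lesions[0].occupancy | gm.searches[0].occupancy)


class TestTable5Fixture:
    def test_row_totals(self):
        assert table5_fixture().row_totals.tolist() == [93, 29, 21, 32]

    def test_column_totals(self):
        assert table5_fixture().col_totals.tolist() == [78, 32, 27, 38]

    def test_grand_total(self):
        assert table5_fixture().grand_total == 175
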