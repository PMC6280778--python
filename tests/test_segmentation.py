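import numpy as np
import pytest
from scipy import ndimage

import acemee as am
from acemee.kinetics import ParametricMaps
from acemee.segmentation import (_border_radii, compute_lvm,
                                 find_slice_midpoints, profile_borders,
                                 segment_lv)


def _synthetic_maps(k1, v_a, v_v=None, voxel=(2.0, 2.0, 10.0)):
    zeros = np.zeros_like(k1)
    return ParametricMaps(k1=k1, k2=zeros.copy(), v_a=v_a,
                          v_v=zeros.copy() if v_v is None else v_v,
                          rss=zeros.copy(),
                          geometry=am.VoxelGeometry(voxel_size=voxel))


class TestProfileBorders:
    def test_top_hat_borders_exact(self):
        prof = np.zeros(100)
        prof[30:61] = 5.0
        assert profile_borders(prof) == (30, 60)

    def test_flat_zero_profile_has_no_borders(self):
        assert profile_borders(np.zeros(50)) is None

    def test_interpolated_crossing_on_linear_ramps(self):
        # ramp up over [10, 20], plateau 1.0, ramp down over [40, 50]
        r = np.arange(60.0)
        prof = np.clip((r - 10) / 10.0, 0, 1) * np.clip((50 - r) / 10.0, 0, 1)
        prof = np.minimum(prof, 1.0)
        endo, epi = _border_radii(prof, r)
        # 2/3 crossings of the ramps: 10 + 20/3 and 50 - 20/3
        assert endo == pytest.approx(10 + 20 / 3, abs=0.51)
        assert epi == pytest.approx(50 - 20 / 3, abs=0.51)


class TestMidpoints:
    def test_symmetric_disc_centroid_is_exact(self):
        va = np.zeros((41, 41, 3))
        xx, yy = np.meshgrid(np.arange(41), np.arange(41), indexing="ij")
        va[(xx - 20) ** 2 + (yy - 20) ** 2 <= 64, :] = 1.0
        maps = _synthetic_maps(np.zeros_like(va), va)
        mids = find_slice_midpoints(maps)
        for m in mids:
            assert m == pytest.approx((20.0, 20.0))

    def test_phantom_cavity_centroid_within_half_voxel(self, noiseless_phantom,
                                                       noiseless_maps):
        spec, _, _ = noiseless_phantom
        mids = find_slice_midpoints(noiseless_maps)
        expect = (spec.lv_center_mm[0] / spec.voxel_size[0] - 0.5,
                  spec.lv_center_mm[1] / spec.voxel_size[1] - 0.5)
        for z in range(*spec.wall_slices):
            assert mids[z] == pytest.approx(expect, abs=0.5)

    def test_all_zero_va_slice_unsegmentable(self):
        maps = _synthetic_maps(np.zeros((10, 10, 2)), np.zeros((10, 10, 2)))
        assert find_slice_midpoints(maps) == [None, None]

    def test_rv_like_component_is_not_selected(self):
        """A high-V_V component (RV cavity) must not define the midpoints."""
        va = np.zeros((40, 40, 1))
        vv = np.zeros((40, 40, 1))
        xx, yy = np.meshgrid(np.arange(40), np.arange(40), indexing="ij")
        lv = (xx - 28) ** 2 + (yy - 20) ** 2 <= 25
        rv = (xx - 8) ** 2 + (yy - 20) ** 2 <= 64  # larger but venous
        va[lv, 0] = 0.95
        va[rv, 0] = 0.6
        vv[rv, 0] = 0.9
        maps = _synthetic_maps(np.zeros_like(va), va, vv)
        (mid,) = find_slice_midpoints(maps)
        assert mid == pytest.approx((28.0, 20.0), abs=0.5)


class TestSegmentLv:
    def test_noiseless_annulus_mass_within_five_percent(self):
        spec = am.PhantomSpec(noise_scale=0.0, psf_fwhm_mm=0.0)
        image, truth = am.simulate_phantom(spec)
        ifs = am.cluster_blood_pools(image)
        from acemee.input_functions import metabolite_correct, parent_fraction_sigmoid
        ifs.c_p = metabolite_correct(ifs.c_a, parent_fraction_sigmoid)
        basis = am.BasisSet.build(ifs.c_p, image.schedule)
        frame_mean = image.values.mean(axis=3)
        maps = am.make_parametric_maps(image, ifs, basis,
                                       frame_mean > 0.05 * frame_mean.max())
        seg = segment_lv(maps, find_slice_midpoints(maps))
        assert seg.lvm_g == pytest.approx(truth.lvm_g, rel=0.05)
        assert seg.lvm_g == pytest.approx(seg.volume_mm3 * 1.05e-3, rel=1e-12)

    def test_intensity_scale_invariance(self, noiseless_maps):
        mids = find_slice_midpoints(noiseless_maps)
        seg1 = segment_lv(noiseless_maps, mids)
        scaled = ParametricMaps(k1=37.0 * noiseless_maps.k1, k2=noiseless_maps.k2,
                                v_a=noiseless_maps.v_a, v_v=noiseless_maps.v_v,
                                rss=noiseless_maps.rss,
                                geometry=noiseless_maps.geometry)
        seg2 = segment_lv(scaled, mids)
        assert np.array_equal(seg1.mask, seg2.mask)

    def test_in_plane_rotation_stability(self, noiseless_phantom):
        """Rotating the phantom 30 deg in-plane changes LVM by < 3%."""
        spec, image, _ = noiseless_phantom
        from acemee.input_functions import metabolite_correct, parent_fraction_sigmoid
        rot = ndimage.rotate(image.values, 30.0, axes=(0, 1), reshape=False,
                             order=1, mode="constant", cval=0.0)
        rot_img = am.DynamicImage(values=rot, schedule=image.schedule,
                                  geometry=image.geometry)

        def lvm_of(img):
            ifs = am.cluster_blood_pools(img)
            ifs.c_p = metabolite_correct(ifs.c_a, parent_fraction_sigmoid)
            basis = am.BasisSet.build(ifs.c_p, img.schedule)
            fm = img.values.mean(axis=3)
            maps = am.make_parametric_maps(img, ifs, basis, fm > 0.05 * fm.max())
            return segment_lv(maps, find_slice_midpoints(maps)).lvm_g

        assert lvm_of(rot_img) == pytest.approx(lvm_of(image), rel=0.03)

    def test_mass_stability_across_noise_seeds(self, control_vitals):
        """LVM coefficient of variation across noisy replicates is small."""
        lvms = []
        for seed in range(6):
            image, truth = am.simulate_phantom(am.PhantomSpec(seed=seed))
            rep = am.run_mee_pipeline(am.PipelineConfig(), image=image,
                                      vitals=control_vitals,
                                      dose_bq=truth.injected_dose_bq)
            lvms.append(rep.result.lvm_g)
        assert np.std(lvms) / np.mean(lvms) < 0.05


def test_long_axis_aligns_with_slice_normal(noiseless_maps):
    from acemee.segmentation import estimate_long_axis
    axis = estimate_long_axis(noiseless_maps)
    assert abs(axis[2]) > 0.99


class TestComputeLvm:
    def test_arithmetic(self):
        mask = np.zeros((20, 10, 10), bool)
        mask.flat[:1000] = True
        geom = am.VoxelGeometry(voxel_size=(2.0, 2.0, 2.0))
        assert compute_lvm(mask, geom) == pytest.approx(8.4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            compute_lvm(np.zeros((5, 5, 5), bool),
                        am.VoxelGeometry(voxel_size=(2.0, 2.0, 2.0)))

    def test_linear_in_voxel_volume(self):
        mask = np.ones((4, 4, 4), bool)
        g1 = am.VoxelGeometry(voxel_size=(2.0, 2.0, 2.0))
        g2 = am.VoxelGeometry(voxel_size=(2.0, 2.0, 4.0))
        assert compute_lvm(mask, g2) == pytest.approx(2.0 * compute_lvm(mask, g1))
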