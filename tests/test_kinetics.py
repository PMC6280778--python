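import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import acemee as am
from acemee.kinetics import mvo2_from_k2
from acemee.phantom import phantom_region_masks
from acemee.input_functions import metabolite_correct, parent_fraction_sigmoid
from scipy.ndimage import binary_erosion


class TestModelTac:
    def test_null_model_is_zero(self, true_inputs, schedule):
        p = am.KineticParameters(k1=0.0, k2=0.1, v_a=0.0, v_v=0.0)
        assert np.all(am.model_tac(p, true_inputs, schedule).values == 0.0)

    def test_pure_blood_voxel_reproduces_arterial_curve(self, true_inputs, schedule):
        p = am.KineticParameters(k1=0.0, k2=0.1, v_a=1.0, v_v=0.0)
        np.testing.assert_allclose(am.model_tac(p, true_inputs, schedule).values,
                                   true_inputs.c_a.values, rtol=1e-12)

    def test_impulse_input_gives_exponential_washout(self):
        """A narrow unit-area plasma pulse at t=0 convolves to ~K1*exp(-k2*t)."""
        dt = 0.001
        starts = np.arange(0.0, 2.0, dt)
        sched = am.FrameSchedule(start_times=starts, durations=np.full_like(starts, dt))
        width = 0.05
        cp_vals = np.where(sched.mid_times <= width, 1.0 / width, 0.0)
        cp = am.TimeActivityCurve.from_schedule(sched, cp_vals)
        zero = am.TimeActivityCurve.from_schedule(sched, np.zeros_like(cp_vals))
        ifs = am.InputFunctionSet(c_a=zero, c_rv=zero, c_p=cp)
        # c_a is zero here, so V_A only scales the tissue term weight
        p = am.KineticParameters(k1=0.3, k2=0.2, v_a=0.0, v_v=0.0)
        tac = am.model_tac(p, ifs, sched, dt=dt / 2)
        late = sched.mid_times > 2 * width
        # the pulse has finite width: washout is delayed by its centroid
        expect = 0.3 * np.exp(-0.2 * (sched.mid_times[late] - width / 2))
        np.testing.assert_allclose(tac.values[late], expect, rtol=0.02)

    def test_linearity_in_coefficients_at_fixed_k2(self, true_inputs, schedule):
        k2 = 0.08
        base = am.model_tac(am.KineticParameters(k1=0.0, k2=k2, v_a=0.0, v_v=0.0),
                            true_inputs, schedule).values
        t_k1 = am.model_tac(am.KineticParameters(k1=0.2, k2=k2, v_a=0.0, v_v=0.0),
                            true_inputs, schedule).values
        t_va = am.model_tac(am.KineticParameters(k1=0.0, k2=k2, v_a=0.3, v_v=0.0),
                            true_inputs, schedule).values
        t_vv = am.model_tac(am.KineticParameters(k1=0.0, k2=k2, v_a=0.0, v_v=0.4),
                            true_inputs, schedule).values
        combo = am.model_tac(
            am.KineticParameters(k1=0.2 / (1 - 0.3), k2=k2, v_a=0.3, v_v=0.4),
            true_inputs, schedule).values
        np.testing.assert_allclose(combo, t_k1 + t_va + t_vv - 2 * base, rtol=1e-9)

    def test_missing_plasma_input_rejected(self, true_inputs, schedule):
        ifs = am.InputFunctionSet(c_a=true_inputs.c_a, c_rv=true_inputs.c_rv)
        p = am.KineticParameters(k1=0.2, k2=0.1, v_a=0.1, v_v=0.0)
        with pytest.raises(ValueError):
            am.model_tac(p, ifs, schedule)


class TestFitSingleCompartment:
    def test_noiseless_recovery_within_one_percent(self, true_inputs, true_basis,
                                                   schedule):
        truth = am.KineticParameters(k1=0.20, k2=0.08, v_a=0.30, v_v=0.10)
        tac = am.model_tac(truth, true_inputs, schedule)
        fit = am.fit_single_compartment(tac, true_inputs, true_basis)
        assert fit.k1 == pytest.approx(truth.k1, rel=0.01)
        assert fit.k2 == pytest.approx(truth.k2, rel=0.01)
        assert fit.v_a == pytest.approx(truth.v_a, rel=0.01)
        assert fit.v_v == pytest.approx(truth.v_v, rel=0.01)

    def test_pure_arterial_blood_tac(self, true_inputs, true_basis, schedule):
        tac = am.TimeActivityCurve.from_schedule(schedule, true_inputs.c_a.values)
        fit = am.fit_single_compartment(tac, true_inputs, true_basis)
        assert fit.v_a == pytest.approx(1.0, abs=0.01)
        assert fit.k1 == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_design_rejected(self, schedule):
        zero = am.TimeActivityCurve.from_schedule(schedule,
                                                  np.zeros(schedule.n_frames))
        ifs = am.InputFunctionSet(c_a=zero, c_rv=zero, c_p=zero)
        basis = am.BasisSet.build(zero, schedule)
        with pytest.raises(ValueError, match="degenerate"):
            am.fit_single_compartment(zero, ifs, basis)

    def test_basis_grid_must_be_positive_increasing(self, true_inputs, schedule):
        with pytest.raises(ValueError):
            am.BasisSet.build(true_inputs.c_p, schedule, k2_min=0.5, k2_max=0.1)


class TestParametricMaps:
    def test_homogeneous_wall_matches_global_fit(self, noiseless_phantom,
                                                 clustered_inputs, noiseless_maps):
        spec, image, _ = noiseless_phantom
        core = binary_erosion(phantom_region_masks(spec)["wall"], iterations=2)
        basis = am.BasisSet.build(clustered_inputs.c_p, image.schedule)
        glob = am.fit_single_compartment(am.extract_tac(image, core),
                                         clustered_inputs, basis)
        k2_vox = noiseless_maps.k2[core]
        # every voxel of a homogeneous region agrees with the global fit
        assert np.all(np.abs(k2_vox / glob.k2 - 1.0) < 0.02)

    def test_blood_voxels_map_to_full_arterial_fraction(self, noiseless_phantom,
                                                        noiseless_maps):
        spec, _, _ = noiseless_phantom
        cavity_core = binary_erosion(phantom_region_masks(spec)["lv_cavity"],
                                     iterations=2)
        assert noiseless_maps.v_a[cavity_core].mean() > 0.95
        assert np.all(noiseless_maps.k1[cavity_core] == 0.0)

    def test_maps_respect_parameter_bounds(self, noiseless_maps):
        assert np.all(noiseless_maps.k1 >= 0)
        assert np.all(noiseless_maps.k2 >= 0)
        assert np.all((noiseless_maps.v_a >= 0) & (noiseless_maps.v_a <= 1))
        assert np.all(noiseless_maps.v_a + noiseless_maps.v_v <= 1 + 1e-9)

    def test_noisy_region_mean_k2_within_five_percent(self):
        """Map-level mean k2 over a homogeneous region, n >= 500 voxels."""
        spec = am.PhantomSpec(seed=11, lv_outer_radius_mm=40.0,
                              rv_center_mm=(20.0, 20.0), rv_radius_mm=10.0)
        image, truth = am.simulate_phantom(spec)
        ifs = am.cluster_blood_pools(image)
        ifs.c_p = metabolite_correct(ifs.c_a, parent_fraction_sigmoid)
        basis = am.BasisSet.build(ifs.c_p, image.schedule)
        frame_mean = image.values.mean(axis=3)
        maps = am.make_parametric_maps(image, ifs, basis,
                                       frame_mean > 0.05 * frame_mean.max())
        core = binary_erosion(phantom_region_masks(spec)["wall"], iterations=2)
        k2s = maps.k2[core]
        assert k2s.size >= 500
        assert k2s.mean() == pytest.approx(truth.k2, rel=0.05)


class TestMvo2Conversion:
    def test_known_values(self):
        assert mvo2_from_k2(0.10) == pytest.approx(0.1254)
        assert mvo2_from_k2(0.0812) == pytest.approx(0.1000, abs=2e-4)

    def test_intercept_flagged_at_zero_washout(self):
        with pytest.warns(RuntimeWarning):
            assert mvo2_from_k2(0.0) == pytest.approx(-0.0096)

    def test_negative_k2_rejected(self):
        with pytest.raises(ValueError):
            mvo2_from_k2(-0.01)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(k2=st.floats(0.02, 0.5), dk=st.floats(0.001, 0.2))
    def test_affine_increments(self, k2, dk):
        assert (mvo2_from_k2(k2 + dk) - mvo2_from_k2(k2)
                == pytest.approx(1.35 * dk, rel=1e-9))
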