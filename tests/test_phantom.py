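import numpy as np
import pytest
from scipy.special import gamma as gamma_fn

import acemee as am
from acemee.phantom import phantom_region_masks


def test_gamma_variate_auc_matches_closed_form(schedule):
    # A=1, alpha=2, beta=0.1 min -> AUC = A*beta^(alpha+1)*Gamma(alpha+1) = 0.002
    curve = am.make_input_function(1.0, 2.0, 0.1, 0.0, 0.5, schedule)
    assert curve.frame_auc() == pytest.approx(0.002, rel=1e-3)
    assert curve.frame_auc() == pytest.approx(
        1.0 * 0.1 ** 3 * gamma_fn(3.0), rel=1e-3)


def test_input_function_is_linear_in_amplitude(schedule):
    c1 = am.make_input_function(1.0, 2.0, 0.1, 0.15, 0.5, schedule)
    c2 = am.make_input_function(2.0, 2.0, 0.1, 0.15, 0.5, schedule)
    np.testing.assert_allclose(c2.values, 2.0 * c1.values, rtol=1e-12)


def test_pure_bolus_decays_to_zero(schedule):
    curve = am.make_input_function(1.0, 2.0, 0.1, 0.0, 0.5, schedule)
    assert curve.values[-1] < 1e-12 * curve.values.max()


def test_invalid_bolus_shape_rejected(schedule):
    with pytest.raises(ValueError):
        am.make_input_function(1.0, -2.0, 0.1, 0.0, 0.5, schedule)
    with pytest.raises(ValueError):
        am.make_input_function(1.0, 2.0, 0.0, 0.0, 0.5, schedule)
    with pytest.raises(ValueError):
        am.make_input_function(1.0, 2.0, 0.1, 1.2, 0.5, schedule)


def test_ground_truth_is_internally_consistent(noiseless_phantom):
    spec, _, truth = noiseless_phantom
    # MEE reproduces the energy balance from its own components, exactly
    assert truth.ew_j == pytest.approx(truth.map_mmhg * truth.fco_ml_min * 1.33e-4)
    assert truth.te_j == pytest.approx(truth.mvo2 * truth.lvm_g * 20.0)
    assert truth.mee_pct == pytest.approx(100.0 * truth.ew_j / truth.te_j)
    # dose consistent with FCO through indicator dilution on the first pass
    assert truth.injected_dose_bq == pytest.approx(
        truth.fco_ml_min * truth.first_pass_auc)
    assert truth.fsv_ml * truth.hr_min == pytest.approx(truth.fco_ml_min)


def test_true_lvm_follows_annulus_geometry(noiseless_phantom):
    _, _, truth = noiseless_phantom
    # pi*(35^2-25^2) mm^2 * 80 mm * 1.05e-3 g/mm^3
    assert truth.lvm_g == pytest.approx(
        np.pi * (35.0 ** 2 - 25.0 ** 2) * 80.0 * 1.05e-3, rel=1e-9)
    assert truth.lvm_g == pytest.approx(158.34, abs=0.01)


def test_same_seed_bit_identical_different_seed_not():
    a1, _ = am.simulate_phantom(am.PhantomSpec(seed=5))
    a2, _ = am.simulate_phantom(am.PhantomSpec(seed=5))
    b, _ = am.simulate_phantom(am.PhantomSpec(seed=6))
    assert np.array_equal(a1.values, a2.values)
    assert not np.array_equal(a1.values, b.values)


def test_unblurred_region_tacs_equal_generating_curves():
    """With PSF = 0 and no noise, region-mean TACs are the generating curves."""
    spec = am.PhantomSpec(noise_scale=0.0, psf_fwhm_mm=0.0)
    image, truth = am.simulate_phantom(spec)
    masks = phantom_region_masks(spec)
    wall_tac = am.extract_tac(image, masks["wall"])
    np.testing.assert_allclose(wall_tac.values, truth.c_wall.values, rtol=1e-9)
    lv_tac = am.extract_tac(image, masks["lv_cavity"])
    np.testing.assert_allclose(lv_tac.values, truth.c_a.values, rtol=1e-9)


def test_wall_curve_matches_forward_model(noiseless_phantom, true_inputs):
    """The rendered wall TAC obeys the one-tissue forward model.

    The model path reconstructs the plasma input by interpolating the
    rebinned frame values, so a few-percent quadrature difference remains
    inside the 5-second bolus frames; after the bolus the two quadratures
    agree closely, and so do the curve areas.
    """
    spec, _, truth = noiseless_phantom
    params = am.KineticParameters(k1=spec.k1, k2=spec.k2, v_a=spec.v_a, v_v=spec.v_v)
    model = am.model_tac(params, true_inputs, spec.schedule)
    atol = 1e-3 * truth.c_wall.values.max()
    np.testing.assert_allclose(model.values, truth.c_wall.values,
                               rtol=0.04, atol=atol)
    late = spec.schedule.mid_times > 1.0
    np.testing.assert_allclose(model.values[late], truth.c_wall.values[late],
                               rtol=5e-3, atol=atol)
    assert model.frame_auc() == pytest.approx(truth.c_wall.frame_auc(), rel=5e-3)


def test_rv_bolus_precedes_arterial_bolus(noiseless_phantom):
    _, _, truth = noiseless_phantom
    t_rv = truth.c_rv.times[np.argmax(truth.c_rv.values)]
    t_a = truth.c_a.times[np.argmax(truth.c_a.values)]
    assert t_rv < t_a


def test_overlapping_regions_rejected():
    spec = am.PhantomSpec(rv_center_mm=(50.0, 64.0))  # collides with the wall
    with pytest.raises(ValueError, match="overlap"):
        am.simulate_phantom(spec)


def test_noise_scales_with_frame_duration():
    """Short frames are noisier: residual SD tracks sqrt(activity/duration)."""
    spec = am.PhantomSpec(seed=0)
    noisy, _ = am.simulate_phantom(spec)
    clean, _ = am.simulate_phantom(am.PhantomSpec(noise_scale=0.0))
    resid = noisy.values - clean.values
    masks = phantom_region_masks(spec)
    wall = masks["wall"]
    short, long_ = 5, 28  # 5 s frame vs 300 s frame
    sd_short = resid[wall][:, short].std()
    sd_long = resid[wall][:, long_].std()
    expect = np.sqrt((clean.values[wall][:, short].mean()
                      / noisy.schedule.durations[short])
                     / (clean.values[wall][:, long_].mean()
                        / noisy.schedule.durations[long_]))
    assert sd_short / sd_long == pytest.approx(expect, rel=0.15)
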