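import warnings

import pytest

import acemee as am
from acemee.input_functions import metabolite_correct, parent_fraction_sigmoid

# sklearn emits a ConvergenceWarning when noiseless pools collapse to few
# distinct TAC shapes; that situation is handled explicitly in the package.
warnings.filterwarnings("ignore", module="sklearn")


@pytest.fixture(scope="session")
def schedule():
    return am.default_frame_schedule()


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = am.PhantomSpec(noise_scale=0.0)
    image, truth = am.simulate_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def true_inputs(noiseless_phantom):
    """Input-function set built from the phantom's generating curves."""
    _, _, truth = noiseless_phantom
    c_p = metabolite_correct(truth.c_a, parent_fraction_sigmoid)
    return am.InputFunctionSet(c_a=truth.c_a, c_rv=truth.c_rv, c_p=c_p)


@pytest.fixture(scope="session")
def true_basis(true_inputs, schedule):
    return am.BasisSet.build(true_inputs.c_p, schedule)


@pytest.fixture(scope="session")
def clustered_inputs(noiseless_phantom):
    """Fully automatic (image-derived) input functions on the noiseless phantom."""
    _, image, _ = noiseless_phantom
    ifs = am.cluster_blood_pools(image)
    c_p = metabolite_correct(ifs.c_a, parent_fraction_sigmoid)
    return am.InputFunctionSet(c_a=ifs.c_a, c_rv=ifs.c_rv, c_p=c_p, masks=ifs.masks)


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_phantom, clustered_inputs):
    _, image, _ = noiseless_phantom
    basis = am.BasisSet.build(clustered_inputs.c_p, image.schedule)
    frame_mean = image.values.mean(axis=3)
    body = frame_mean > 0.05 * frame_mean.max()
    return am.make_parametric_maps(image, clustered_inputs, basis, body)


@pytest.fixture(scope="session")
def control_vitals():
    """Healthy-control vitals at the −1/+1/+5 min measurement scheme."""
    return am.VitalsRecord(timepoints_min=[-1.0, 1.0, 5.0],
                           sbp_mmhg=[124.0, 124.0, 124.0],
                           dbp_mmhg=[79.0, 79.0, 79.0],
                           hr_min=[62.0, 62.0, 62.0],
                           map_mmhg=[97.0, 97.0, 97.0])


@pytest.fixture(scope="session")
def run_default_pipeline():
    def _run(image, truth, vitals):
        return am.run_mee_pipeline(am.PipelineConfig(), image=image,
                                   vitals=vitals, dose_bq=truth.injected_dose_bq)
    return _run
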