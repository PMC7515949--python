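import warnings

import numpy as np
import pytest

from petidif import (
    InputFunction,
    extract_factors,
    default_phantom_spec,
    make_basis,
    reference_mouse_schedule,
    render_phantom,
)
from petidif.io import Curve


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    # slow ALS tails on noisy data are expected and flagged on the model
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="factor refinement did not converge")
        yield


@pytest.fixture(scope="session")
def schedule():
    return reference_mouse_schedule()


@pytest.fixture(scope="session")
def noiseless_phantom():
    """The pure 4-source phantom: no PSF blur, no noise."""
    return render_phantom(default_phantom_spec(noise_scale=0.0, psf_fwhm=0.0))


@pytest.fixture(scope="session")
def blurred_phantom():
    """Noiseless phantom degraded by the 1.6 mm scanner PSF."""
    return render_phantom(default_phantom_spec(noise_scale=0.0))


@pytest.fixture(scope="session")
def noisy_phantom():
    """The standard degraded phantom: PSF blur plus frame-dependent noise."""
    return render_phantom(default_phantom_spec(rng_seed=0))


def input_function_from_truth(truth, schedule) -> InputFunction:
    """Ground-truth input function, metabolite-free, on the fine grid."""
    fine = truth.input_fine
    return InputFunction(
        fine.times, fine.values, schedule, parent_plasma=fine.values
    )


@pytest.fixture(scope="session")
def truth_ifn(noiseless_phantom, schedule):
    _, truth = noiseless_phantom
    return input_function_from_truth(truth, schedule)


@pytest.fixture(scope="session")
def truth_basis(truth_ifn, schedule):
    return make_basis(truth_ifn, schedule)


@pytest.fixture(scope="session")
def blood_template(noiseless_phantom, schedule):
    """True blood curve as a P3 template (cheap stand-in for the
    presaturation-derived template in unit tests)."""
    _, truth = noiseless_phantom
    return Curve(schedule.mids, truth.factor_curves[0], unit="arb")


@pytest.fixture(scope="session")
def tracer_model(noiseless_phantom, blood_template):
    image, _ = noiseless_phantom
    return extract_factors(image, mode="tracer", template=blood_template)


def hungarian_cosines(truth_curves: np.ndarray, est_curves: np.ndarray) -> np.ndarray:
    """Best-match cosine similarity between truth and estimated factor curves."""
    from scipy.optimize import linear_sum_assignment

    K = truth_curves.shape[0]
    C = np.zeros((K, est_curves.shape[0]))
    for i in range(K):
        for j in range(est_curves.shape[0]):
            denom = np.linalg.norm(truth_curves[i]) * np.linalg.norm(est_curves[j])
            C[i, j] = truth_curves[i] @ est_curves[j] / (denom + 1e-300)
    rows, cols = linear_sum_assignment(-C)
    return C[rows, cols]
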