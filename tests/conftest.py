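import numpy as np
import pytest

import skinfab as sf


@pytest.fixture(scope="session")
def basis() -> sf.PigmentBasis:
    return sf.default_basis()


@pytest.fixture(scope="session")
def palm(basis):
    """Palm-like phantom and its noiseless render, shared across tests."""
    conc = sf.make_phantom("palm_like", 128, 128, seed=3)
    return conc, sf.render_skin(conc, basis)


@pytest.fixture(scope="session")
def patch_set(basis) -> sf.PatchSet:
    return sf.build_patch_set(30, 30, basis)


@pytest.fixture(scope="session")
def measured_set(patch_set) -> sf.PatchSet:
    return sf.measure_patch_set(patch_set, seed=0)


@pytest.fixture(scope="session")
def planted_set(measured_set) -> sf.PatchSet:
    """Measured patches whose CMYK targets follow the log-linear model class."""
    coef_mel = np.array(
        [
            [0.05, -0.10, 0.02, 0.30],
            [-0.08, 0.03, 0.06, 0.40],
            [0.02, 0.09, -0.07, 0.35],
            [-0.04, -0.05, 0.08, 0.25],
        ]
    )
    return sf.plant_linear_targets(measured_set, coef_mel, coef_mel * 0.8)
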