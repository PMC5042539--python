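"""Shared fixtures: the default model, its baseline, and cached dose runs."""

import numpy as np
import pytest

import ketoflux as kf


@pytest.fixture(scope="session")
def fixture():
    return kf.default_fixture()


@pytest.fixture(scope="session")
def model(fixture):
    return kf.build_model(fixture)


@pytest.fixture(scope="session")
def baseline(model):
    return kf.equilibrate(model)


@pytest.fixture(scope="session")
def blood_bhb_index(model):
    state = model.find_state(kf.Compartment.BLOOD, kf.Substance.BHB)
    return model.state_index()[state.id]


@pytest.fixture(scope="session")
def grid():
    return kf.default_grid()


@pytest.fixture(scope="session")
def dosed_runs(model, baseline, grid):
    """Full-model simulations at the two study dose levels."""
    return {
        dose: kf.simulate(model, kf.DoseEvent(dose), grid, baseline=baseline)
        for dose in (192.0, 573.0)
    }


@pytest.fixture(scope="session")
def noise_free_dataset(fixture):
    from ketoflux.synth import StudyDesign, generate

    return generate(StudyDesign(proportional_cv=0.0, additive_sd_mM=0.0, seed=1), fixture)
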