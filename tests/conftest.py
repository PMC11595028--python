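import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adipospec as a
from adipospec.preprocess import postprocess_mean_spectrum

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library():
    return a.default_library()


@pytest.fixture(scope="session")
def raman_sim():
    """Default synthetic Raman cube (seed 42) with ground truth + registry."""
    cube, layout, registry = a.simulate_cube("raman", seed=42)
    return cube, layout, registry


@pytest.fixture(scope="session")
def raman_e2e(raman_sim):
    """Preprocessed + KMCA(k=4) + named segmentation of the default cube."""
    cube, layout, registry = raman_sim
    preprocessed, log = a.preprocess_raman_cube(cube)
    result = a.assign_compartments(a.kmca(preprocessed, k=4, seed=0))
    return preprocessed, result, log


@pytest.fixture(scope="session")
def ftir_sim():
    """Default synthetic FTIR cube (seed 7) with ground truth + registry."""
    cube, layout, registry = a.simulate_cube("ftir", seed=7)
    return cube, layout, registry


@pytest.fixture(scope="session")
def ftir_e2e(ftir_sim):
    cube, layout, registry = ftir_sim
    preprocessed, mask, log = a.preprocess_ftir_cube(cube)
    result = a.assign_compartments(a.uhca(preprocessed, n_classes=3,
                                          mask=mask, seed=0))
    return preprocessed, mask, result


@pytest.fixture(scope="session")
def ld_unsaturation(raman_e2e):
    """End-to-end LD unsaturation readout of the default Raman cube."""
    _, result, _ = raman_e2e
    ld_mean = postprocess_mean_spectrum(result.spectrum_for("lipid_droplet"))
    model = a.build_unsaturation_calibration()
    return a.unsaturation_from_spectrum(ld_mean, model).value
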