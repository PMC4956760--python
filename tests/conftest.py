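import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from nanoxrf import (FitModel, InstrumentConfig, SampleModel, TissueProfile,
                     fit_spectrum, simulate_reference_spectrum)
from nanoxrf.pipeline import default_reference, run_pipeline

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def instrument():
    return InstrumentConfig()


@pytest.fixture(scope="session")
def tissue():
    return SampleModel()


@pytest.fixture(scope="session")
def quiet_instrument():
    """Instrument with continuum and scatter switched off (line-only spectra)."""
    return InstrumentConfig(scatter_scale=0.0)


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def reference_fit(instrument, reference):
    """Fitted 500-s reference-standard acquisition (shared across tests)."""
    spec = simulate_reference_spectrum(reference, instrument, 500.0, seed=3)
    model = FitModel(instrument=instrument,
                     sample=SampleModel.from_reference(reference))
    return fit_spectrum(spec, model)


@pytest.fixture(scope="session")
def normothermic_run():
    """Full pipeline on the 128x128 normothermic phantom (seed 7)."""
    return run_pipeline("normothermic", shape=(128, 128), seed=7)


@pytest.fixture(scope="session")
def hyperthermic_run():
    """Full pipeline on the 128x128 hyperthermic phantom (seed 11)."""
    return run_pipeline("hyperthermic", shape=(128, 128), seed=11,
                        with_mining=False)


@pytest.fixture(scope="session")
def untreated_run():
    """Full pipeline on a 64x64 untreated phantom (truth Pt = 0)."""
    return run_pipeline("untreated", shape=(64, 64), seed=5, with_mining=False)
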