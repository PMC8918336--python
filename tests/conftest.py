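import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from kmindex.core import (
    MTICI,
    PerfusionVolumes,
    TreatmentRecord,
)
from kmindex.simulate import GeneratorConfig, generate_cohort

#: Mean perfusion volumes of the derivation cohort, cm^3.
COHORT_MEAN_VOLUMES = dict(v_core=53.81, v_penumbra=87.77, v_mtt=950.27, v_mip=1086.26)


@pytest.fixture
def mean_volumes() -> PerfusionVolumes:
    return PerfusionVolumes(**COHORT_MEAN_VOLUMES)


@pytest.fixture
def mtici3_no_rtpa() -> TreatmentRecord:
    return TreatmentRecord(thrombectomy_performed=True, mtici=MTICI.G3, rtpa=False)


@pytest.fixture(scope="session")
def small_cohort():
    """A 120-patient synthetic cohort shared across read-only tests."""
    return generate_cohort(GeneratorConfig(n=120, seed=11))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
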