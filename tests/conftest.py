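import numpy as np
import pytest
from hypothesis import settings

from msofa import PhysiologySnapshot

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_snapshot(**overrides) -> PhysiologySnapshot:
    """A fully normal snapshot (MSOFA and SOFA totals both 0) to perturb."""
    base = dict(
        patient_id="p1",
        timepoint="T0",
        spo2=99.0,
        fio2=0.21,
        on_respiratory_support=False,
        bleeding_sign="none",
        map=85.0,
        dopamine=0.0,
        dobutamine=0.0,
        epinephrine=0.0,
        norepinephrine=0.0,
        jaundice="none",
        gcs=15,
        urine_output_per_kg=1.2,
        pao2=95.0,
        platelets=250.0,
        bilirubin=0.6,
        creatinine=0.9,
        urine_output_daily=1800.0,
    )
    base.update(overrides)
    return PhysiologySnapshot(**base)


@pytest.fixture
def normal_snapshot():
    return make_snapshot()


@pytest.fixture
def worst_snapshot():
    """Every organ at its worst band for both instruments."""
    return make_snapshot(
        spo2=60.0,
        fio2=0.6,  # SpO2/FiO2 = 100
        on_respiratory_support=True,
        bleeding_sign="spontaneous_bleeding",
        map=40.0,
        norepinephrine=0.5,
        jaundice="skin",
        gcs=3,
        urine_output_per_kg=0.0,
        pao2=50.0,  # PaO2/FiO2 = 83
        platelets=10.0,
        bilirubin=15.0,
        creatinine=6.0,
        urine_output_daily=50.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20161225)
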