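import numpy as np
import pytest

from spineplan import (
    CurveSpec,
    PatientParams,
    compute_all,
    generate_spine,
    index_patient_fixture,
)


@pytest.fixture(scope="session")
def index_model():
    """Calibrated preoperative index patient (Lenke 2B pattern)."""
    return index_patient_fixture()


@pytest.fixture(scope="session")
def preop_descriptors(index_model):
    return compute_all(index_model)


def make_params(pt=0.0, mt=0.0, tll=0.0, kyph=0.0, lord=0.0,
                rot_pt=0.0, rot_mt=0.0, rot_tll=0.0, **kw) -> PatientParams:
    """Convenience constructor with the index patient's region layout."""
    return PatientParams(
        curves=[
            CurveSpec("PT", "T1", "T3", "T5", pt, "left", rot_pt),
            CurveSpec("MT", "T5", "T8", "T11", mt, "right", rot_mt),
            CurveSpec("TL/L", "T11", "L2", "L4", tll, "left", rot_tll),
        ],
        kyphosis_amplitude=kyph, lordosis_amplitude=lord, **kw)


@pytest.fixture(scope="session")
def straight_model():
    return generate_spine(make_params())
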