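import numpy as np
import pytest

from fickco import MethodPair, PatientRecord, Sex


@pytest.fixture
def record():
    """A complete, physiologically plausible patient."""
    return PatientRecord(
        patient_id="P001",
        age=60.0,
        sex=Sex.MALE,
        height=180.0,
        weight=75.0,
        hemoglobin=15.0,
        sao2=0.98,
        svo2=0.68,
        heart_rate=70.0,
        td_co=5.4,
        mpap=22.0,
        mpawp=13.0,
    )


@pytest.fixture
def toy_pair():
    """The hand-computed triple: diffs (1, 0, -1), mean_diff 0, SD 1."""
    return MethodPair.from_series("ref", [5.0, 6.0, 7.0], "cmp", [4.0, 6.0, 8.0])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
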