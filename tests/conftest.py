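import pytest
from hypothesis import settings

from petquant.dosimetry import DoseRecord
from petquant.phantom import build_phantom, default_mouse_organs

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dose_record():
    """150 μCi assayed 08:30, 20 μCi residual after 09:00 injection, scan 09:45."""
    return DoseRecord(
        initial_dose=150.0,
        residual_dose=20.0,
        initial_time="8.30",
        injection_time="9.00",
        scan_time="9.45",
        weight=20.0,
    )


@pytest.fixture(scope="session")
def no_gap_dose():
    """100 μCi with coincident assay/injection/scan times: no decay, no residual."""
    return DoseRecord(
        initial_dose=100.0,
        residual_dose=0.0,
        initial_time="9.00",
        injection_time="9.00",
        scan_time="9.00",
        weight=20.0,
    )


@pytest.fixture(scope="session")
def mouse_phantom():
    """The default six-organ mouse with reference uptake as ground truth."""
    return build_phantom(default_mouse_organs())
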