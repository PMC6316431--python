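import pytest
from hypothesis import settings

from somaqc.simulate import make_fixture_small

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def fixture_small():
    """Canonical small simulated run: 2 plates, 16 study wells, 28 analytes."""
    return make_fixture_small(seed=0)


@pytest.fixture(scope="session")
def cascade(fixture_small):
    """Fixture run through the full normalization cascade."""
    from somaqc.normalize import (
        calibration_normalize,
        hybridization_normalize,
        median_signal_normalize,
    )

    dataset, truth, elisa = fixture_small
    d1, hyb = hybridization_normalize(dataset)
    d2, med = median_signal_normalize(d1)
    d3, cal = calibration_normalize(d2)
    return {
        "raw": dataset,
        "truth": truth,
        "elisa": elisa,
        "normalized": d3,
        "hyb": hyb,
        "median": med,
        "cal": cal,
    }
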