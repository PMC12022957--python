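import pytest

from sixmwt import calibration_preset, generate_cohort


@pytest.fixture(scope="session")
def calibration_cohort():
    """One fixed synthetic study-emulating cohort (26 cases / 28 controls)."""
    return generate_cohort(calibration_preset(seed=1))
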