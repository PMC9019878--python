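import pytest

from thyrisk.reference import reference_cohort


@pytest.fixture(scope="session")
def resected():
    """The 58-nodule resected reference cohort with histology and calls."""
    return reference_cohort(resected_only=True)


@pytest.fixture(scope="session")
def full_cohort():
    """All 140 reference nodules, resected and not."""
    return reference_cohort()
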