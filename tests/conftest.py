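import numpy as np
import pytest

from epiage import AssayDistortion, default_age_functions, load_default_panel
from epiage.panel import collapsed_references


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def refs(panel):
    return collapsed_references(panel)


@pytest.fixture(scope="session")
def blood_functions(panel):
    return default_age_functions(panel, "blood")


@pytest.fixture()
def clean_assay():
    """No bias, no noise, perfect conversion, no sequencing error."""
    return AssayDistortion.none()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
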