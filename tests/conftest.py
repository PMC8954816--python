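import numpy as np
import pytest

from dmpkit import (
    DAPORINAD,
    GeneratorConfig,
    Peak,
    enumerate_chains,
    reference_metabolites,
)


@pytest.fixture(scope="session")
def reference():
    """The corrected 26-entry metabolite characterization set."""
    return reference_metabolites()


@pytest.fixture(scope="session")
def reference_peaks(reference):
    """Peak list transcribed from the published m/z and rt columns."""
    return [Peak("mouse_plasma", r.rt, r.mz, 1.0e5) for r in reference]


@pytest.fixture(scope="session")
def default_chains():
    return enumerate_chains(DAPORINAD, max_steps=3)


@pytest.fixture()
def config():
    return GeneratorConfig(seed=0)
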