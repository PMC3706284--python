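import pytest

from deafscreen.catalogue import load_catalogue
from deafscreen.pipeline import run_screen


@pytest.fixture(scope="session")
def cat():
    return load_catalogue()


@pytest.fixture(scope="session")
def refs(cat):
    return cat.references


@pytest.fixture(scope="session")
def screen():
    """One full pipeline run on the fixture cohort, shared by the suite."""
    return run_screen(seed=1)
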