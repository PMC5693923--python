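import pytest
from hypothesis import settings

from fbgscan import FBGDomain, load_catalog, load_reference

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from fbgscan.fixtures import build_domain_standins, build_synthetic_frep_records


@pytest.fixture(scope="session")
def annotation():
    return load_reference()


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()


@pytest.fixture(scope="session")
def standins():
    return build_domain_standins()


@pytest.fixture(scope="session")
def standin_records():
    return {r.id: r for r in build_synthetic_frep_records()}


@pytest.fixture(scope="session")
def reference_domain(annotation):
    return FBGDomain(id="FBG-C", sequence=annotation.sequence)
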