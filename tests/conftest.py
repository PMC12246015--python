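import pytest

from scaffoldmech import ScaffoldSpec, build_layout, step1_designs


@pytest.fixture(scope="session")
def base_spec() -> ScaffoldSpec:
    """The original scaffold: 10 x 4.8 mm envelope, 700 um strands, 7 x 9."""
    return ScaffoldSpec(name="S0-H7-V9")


@pytest.fixture(scope="session")
def step1(base_spec):
    return step1_designs(base_spec)


@pytest.fixture(scope="session")
def base_layout(base_spec):
    return build_layout(base_spec)
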