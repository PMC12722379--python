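import pytest

from wolbachia_households import (
    build_generator,
    full_params,
    tutorial_params,
)


@pytest.fixture(scope="session")
def tut_params():
    return tutorial_params()


@pytest.fixture(scope="session")
def fullp():
    return full_params()


@pytest.fixture(scope="session")
def tut_gen(tut_params):
    return build_generator(tut_params)


@pytest.fixture(scope="session")
def full_gen(fullp):
    return build_generator(fullp)


@pytest.fixture(scope="session")
def full_gen_v09():
    return build_generator(full_params(v=0.9))
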