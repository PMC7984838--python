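import pytest

import plaidpss as pp


@pytest.fixture(scope="session")
def streaming_set():
    return pp.build_streaming_set(reps=10)


@pytest.fixture(scope="session")
def classic_set():
    return pp.build_classic_set()


@pytest.fixture(scope="session")
def young_bank():
    return pp.build_v1_bank(pp.v1_profile_preset("young"))


@pytest.fixture(scope="session")
def middle_bank():
    return pp.build_v1_bank(pp.v1_profile_preset("middle"))
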