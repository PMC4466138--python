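import pytest

from fingertrap.repeats import make_ideal_repeat, make_chain


@pytest.fixture(scope="session")
def ideal_repeat():
    return make_ideal_repeat(seed=1)


@pytest.fixture(scope="session")
def two_repeat_template(ideal_repeat):
    return make_chain(ideal_repeat, 2)
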