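import pytest

from jackprod.semigroup import make_bitstring_or, make_integer_add, make_integer_max


@pytest.fixture
def add():
    return make_integer_add()


@pytest.fixture
def imax():
    return make_integer_max()


@pytest.fixture
def bit4():
    return make_bitstring_or(4)


@pytest.fixture
def fig_input():
    """The six-element worked example, under integer addition (total 33)."""
    return [5, 8, 6, 3, 4, 7]
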