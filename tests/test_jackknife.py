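"""The three-phase jackknife-product algorithm, pinned by two oracles."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jackprod.convolution import TruncatedArray, convolution_semigroup
from jackprod.jackknife import (
    IndexScheme,
    aunt,
    downward_phase,
    jackknife_products,
    naive_jackknife,
    pad_to_power,
    rho,
    segment_product,
    segment_tree_jackknife,
    tau,
    transposition_phase,
    upward_phase,
)
from jackprod.semigroup import (
    InstrumentedSemigroup,
    fold_product,
    make_bitstring_or,
    make_integer_add,
    make_integer_max,
    make_string_concat,
)


# ---------------------------------------------------------------- index maps

@pytest.mark.parametrize("j, expected", [(0, 0), (5, 2), (4, 2)])
def test_rho(j, expected):
    assert rho(j) == expected


def test_tau_swaps_adjacent_pairs_and_is_involutive():
    assert [tau(j) for j in range(4)] == [1, 0, 3, 2]
    assert tau(6) == 7 and tau(7) == 6
    for j in range(100):
        assert tau(tau(j)) == j


@pytest.mark.parametrize(
    "n, k, j, expected",
    [
        (8, 1, 0, 1),  # aunt of the first leaf pair is its parent's sibling
        (8, 1, 1, 1),
        (3, 1, 2, 0),  # odd-row top: clamped/transposed down
        (5, 2, 2, 0),
    ],
)
def test_aunt_index(n, k, j, expected):
    assert aunt(IndexScheme(n), k, j) == expected


def test_aunt_rejects_out_of_range():
    with pytest.raises(ValueError):
        aunt(IndexScheme(8), 1, 8)


def test_index_scheme_row_lengths():
    for n in range(2, 200):
        s = IndexScheme(n)
        lengths = s.row_lengths()
        assert lengths[0] == n
        assert lengths[-1] == 2
        for k, nk in enumerate(lengths):
            assert 0 <= nk - n * 2 ** (-k) < 1


# ---------------------------------------------------------- worked example

def test_upward_phase_worked_example(add, fig_input):
    tree = upward_phase(add, pad_to_power(add, fig_input))
    assert tree.rows[1][0] == 13
    assert tree.rows[2] == [22, 11]


def test_upward_phase_two_elements_has_single_row(add):
    tree = upward_phase(add, [3, 9])
    assert tree.rows == [[3, 9]]


def test_downward_phase_worked_example(add, fig_input):
    tree = upward_phase(add, pad_to_power(add, fig_input))
    bar = downward_phase(add, tree)
    assert bar[1][0] == 24 and bar[1][1] == 20
    assert bar[0] == [25, 28, 30, 27, 26, 29, 33, 33]


def test_downward_phase_n3_symbolic():
    # string multisets stand in for formal sums: sorted concatenation is a
    # commutative semigroup, so the n=3 complementary row is (ac, bc, ab)
    S = make_sorted_concat()
    tree = upward_phase(S, list("abc"))
    bar = downward_phase(S, tree)
    assert bar[0] == ["ac", "bc", "ab"]


def make_sorted_concat():
    from jackprod.semigroup import SemigroupSpec

    return SemigroupSpec(
        product=lambda a, b: "".join(sorted(a + b)), identity="", label="msort"
    )


def test_transposition_phase_worked_example():
    row = [25, 28, 30, 27, 26, 29, 33, 33]
    assert transposition_phase(row, 8) == [28, 25, 27, 30, 29, 26, 33, 33]
    assert transposition_phase(["x", "y"], 2) == ["y", "x"]
    assert transposition_phase(["ac", "bc", "ab"], 3) == ["bc", "ac", "ab"]


def test_transposition_is_self_inverse_on_even_rows():
    row = list(range(10))
    assert transposition_phase(transposition_phase(row, 10), 10) == row


def test_full_algorithm_worked_example(add, fig_input):
    res = jackknife_products(add, fig_input)
    assert res.jackknife == [28, 25, 27, 30, 29, 26]
    assert res.full_product == 33
    # integer-addition closed form: each jackknife value plus its input is ḡ
    assert all(j + g == 33 for j, g in zip(res.jackknife, fig_input))


@pytest.mark.parametrize("n", [0, 1, 2])
def test_degenerate_sizes(add, n):
    g = [7, 9][:n]
    res = jackknife_products(add, g)
    assert res.n == n
    if n == 0:
        assert res.jackknife == []
    elif n == 1:
        assert res.jackknife == [0]  # empty leave-one-out product = identity
    else:
        assert res.jackknife == [9, 7]


def test_unit_bitstrings_give_complement_pattern():
    S = make_bitstring_or(4)
    res = jackknife_products(S, ["1000", "0100", "0010", "0001"])
    assert res.jackknife == ["0111", "1011", "1101", "1110"]


# ------------------------------------------------------------------ padding

def test_pad_to_power(add, fig_input):
    assert pad_to_power(add, fig_input) == [5, 8, 6, 3, 4, 7, 0, 0]
    assert pad_to_power(add, [1, 2, 3, 4]) == [1, 2, 3, 4]
    assert pad_to_power(add, [1] * 5) == [1, 1, 1, 1, 1, 0, 0, 0]


def test_padding_equivalence(add):
    rng = random.Random(5)
    for n in range(1, 34):
        g = [rng.randint(0, 50) for _ in range(n)]
        unpadded = jackknife_products(add, g).jackknife
        padded = jackknife_products(add, pad_to_power(add, g)).jackknife
        assert unpadded == padded[:n]


# ------------------------------------------------------------ product count

def test_product_count_closed_form_at_binary_powers(add):
    for m in range(1, 13):
        n = 1 << m
        res = jackknife_products(add, list(range(n)))
        assert res.product_count == 3 * n - 6


def test_product_count_bound_general_n(add):
    rng = random.Random(11)
    for _ in range(200):
        n = rng.randint(2, 5000)
        res = jackknife_products(add, [1] * n)
        m = (n - 1).bit_length()
        assert res.product_count <= 3 * n + 2 * m


def test_phase_split_of_product_count(add):
    # upward n−2 and downward 2n−4 at binary powers
    n = 64
    inst = InstrumentedSemigroup(add)
    tree = upward_phase(inst, list(range(n)))
    assert inst.product_count == n - 2
    downward_phase(inst, tree)
    assert inst.product_count == (n - 2) + (2 * n - 4)


# -------------------------------------------------------------- in-place

def test_in_place_gives_identical_results(add):
    rng = random.Random(23)
    for n in range(2, 40):
        g = [rng.randint(0, 99) for _ in range(n)]
        a = jackknife_products(add, g, in_place=False)
        b = jackknife_products(add, g, in_place=True)
        assert a.jackknife == b.jackknife
        assert a.product_count == b.product_count


def test_in_place_overwrites_tree_not_a_third_structure(add):
    g = list(range(16))
    inst = InstrumentedSemigroup(add)
    tree = upward_phase(inst, g)
    rows_before = tree.rows
    bar = downward_phase(inst, tree, in_place=True)
    assert bar is tree.rows  # same storage: ~2n elements total
    assert rows_before is tree.rows


# ------------------------------------------------------- oracle equivalence

def _random_instance(rng, which, n):
    if which == "add":
        return make_integer_add(), [rng.randint(0, 99) for _ in range(n)]
    if which == "max":
        return make_integer_max(), [rng.randint(0, 99) for _ in range(n)]
    if which == "or":
        return make_bitstring_or(6), [format(rng.getrandbits(6), "06b") for _ in range(n)]
    K = rng.randint(0, 6)
    arrays = [
        TruncatedArray(K, tuple(rng.randint(0, 5) for _ in range(K + 1)), "int")
        for _ in range(n)
    ]
    return convolution_semigroup(K, "int"), arrays


@pytest.mark.parametrize("which", ["add", "max", "or", "conv"])
def test_oracle_equivalence_random_instances(which):
    """Three independent algorithms agree element-wise on seeded inputs."""
    rng = random.Random({"add": 1, "max": 2, "or": 3, "conv": 4}[which])
    eq_cases = 50
    for _ in range(eq_cases):
        n = rng.randint(1, 40)
        S, g = _random_instance(rng, which, n)
        fast = jackknife_products(S, g).jackknife
        naive = naive_jackknife(S, g)
        segt = segment_tree_jackknife(S, g)
        eq = S.equality
        assert all(eq(a, b) for a, b in zip(fast, naive))
        assert all(eq(a, b) for a, b in zip(fast, segt))
        padded = jackknife_products(S, pad_to_power(S, g)).jackknife[:n] if n else []
        assert all(eq(a, b) for a, b in zip(fast, padded))


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=10**6), min_size=1, max_size=64))
def test_addition_closed_form_property(g):
    """Over integer addition, ḡ_j = ḡ − g_j for every j."""
    res = jackknife_products(make_integer_add(), g)
    total = sum(g)
    assert res.full_product == total
    assert res.jackknife == [total - x for x in g]


# ------------------------------------------------------------ segment tree

def test_segment_product_examples(add, fig_input):
    tree = upward_phase(add, pad_to_power(add, fig_input))
    assert segment_product(add, tree, 0, 2) == 13
    assert segment_product(add, tree, 3, 3) == 0
    assert segment_product(add, tree, 0, 8) == 33


def test_segment_product_matches_fold_on_all_ranges(add):
    rng = random.Random(7)
    for n in (2, 3, 5, 8, 11, 16, 17):
        g = [rng.randint(0, 99) for _ in range(n)]
        tree = upward_phase(add, g)
        for i in range(n + 1):
            for j in range(i, n + 1):
                assert segment_product(add, tree, i, j) == sum(g[i:j])


def test_segment_product_rejects_bad_ranges(add):
    tree = upward_phase(add, [1, 2, 3, 4])
    with pytest.raises(ValueError):
        segment_product(add, tree, 3, 2)
    with pytest.raises(ValueError):
        segment_product(add, tree, 0, 5)


def test_segment_tree_oracle_preserves_order_without_commutativity():
    S = make_string_concat()
    assert segment_tree_jackknife(S, ["a", "b", "c"]) == ["bc", "ac", "ab"]
    rng = random.Random(2)
    for n in range(1, 20):
        g = [chr(97 + rng.randrange(26)) for _ in range(n)]
        assert segment_tree_jackknife(S, g) == naive_jackknife(S, g)
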