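"""Tandemer algebra: feasibility, marginalization, Cauchy products, marginals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemer.errors import ValidationError
from tandemer.iso_core import (
    MFP,
    IsotopomerDistribution,
    TandemerMatrix,
    cauchy_product,
    clamp_small_negatives,
    feasible_mask,
    is_feasible,
    n_feasible,
    parent_mid,
    product_mid,
    tandemer_from_isotopomers,
)

from conftest import direct_fragment_mid

# the worked example: 4-carbon metabolite, parent {2,3,4}, product {2,3}
WORKED_MFP = MFP("A", (2, 3, 4), (2, 3))
WORKED_DIST = IsotopomerDistribution.from_patterns(
    "A", 4, {"1001": 0.6, "0101": 0.3, "1011": 0.1}
)


@pytest.mark.parametrize(
    "i,j,np_,nk,expected",
    [
        (1, 0, 3, 2, True),  # the [M+1] > [m+0] transition of the worked example
        (3, 0, 3, 2, False),  # j below i - (|N|-|K|)
        (0, 0, 3, 2, True),
        (0, 0, 5, 0, True),
        (2, 2, 3, 2, True),
        (1, 2, 3, 2, False),  # product cannot carry more labels than parent
    ],
)
def test_is_feasible(i, j, np_, nk, expected):
    assert is_feasible(i, j, np_, nk) is expected


def test_is_feasible_rejects_out_of_range():
    with pytest.raises(ValidationError):
        is_feasible(4, 0, 3, 2)
    with pytest.raises(ValidationError):
        is_feasible(0, 3, 3, 2)


@pytest.mark.parametrize("n_parent", range(0, 11))
def test_n_feasible_matches_enumeration(n_parent):
    """The closed form (|N|-|K|+1)(|K|+1) counts exactly the feasible grid."""
    for n_product in range(n_parent + 1):
        brute = sum(
            is_feasible(i, j, n_parent, n_product)
            for i in range(n_parent + 1)
            for j in range(n_product + 1)
        )
        assert n_feasible(n_parent, n_product) == brute
        assert feasible_mask(n_parent, n_product).sum() == brute


def test_n_feasible_examples():
    assert n_feasible(3, 2) == 6
    assert n_feasible(5, 2) == 12
    for k in range(5):
        assert n_feasible(k, k) == k + 1
    with pytest.raises(ValidationError):
        n_feasible(2, 3)


def test_marginalization_worked_example():
    t = tandemer_from_isotopomers(WORKED_DIST, WORKED_MFP)
    expected = np.zeros((4, 3))
    expected[1, 0] = 0.6
    expected[2, 1] = 0.4
    np.testing.assert_allclose(t.values, expected, atol=1e-15)


def test_marginalization_unlabeled_delta():
    dist = IsotopomerDistribution.from_patterns("A", 4, {"0000": 1.0})
    t = tandemer_from_isotopomers(dist, WORKED_MFP)
    assert t.values[0, 0] == 1.0
    assert t.values.sum() == 1.0


def test_marginalization_uniform_distribution():
    """Counting isotopomers per tandemer cell for the uniform distribution."""
    dist = IsotopomerDistribution("A", np.full(16, 1 / 16))
    t = tandemer_from_isotopomers(dist, WORKED_MFP)
    expected = np.zeros((4, 3))
    expected[0, 0] = 2 / 16
    expected[1, 0] = 2 / 16
    expected[1, 1] = 4 / 16
    expected[2, 1] = 4 / 16
    expected[2, 2] = 2 / 16
    expected[3, 2] = 2 / 16
    np.testing.assert_allclose(t.values, expected)


def test_marginalization_rejects_out_of_range_atoms():
    with pytest.raises(ValidationError):
        tandemer_from_isotopomers(WORKED_DIST, MFP("A", (2, 3, 5), (2, 3)))


def test_empty_product_fragment_is_parent_mid():
    mfp = MFP("A", (2, 3, 4), ())
    t = tandemer_from_isotopomers(WORKED_DIST, mfp)
    assert t.values.shape == (4, 1)
    np.testing.assert_allclose(t.values[:, 0], parent_mid(
        tandemer_from_isotopomers(WORKED_DIST, WORKED_MFP)))


def test_cauchy_product_delta():
    delta = TandemerMatrix(np.array([[1.0]]))
    out = cauchy_product(delta, delta)
    np.testing.assert_array_equal(out.values, [[1.0]])


def test_cauchy_product_hand_expansion():
    a = TandemerMatrix(np.array([[0.5, 0.0], [0.0, 0.5]]))
    c = cauchy_product(a, a)
    expected = np.zeros((3, 3))
    expected[0, 0], expected[1, 1], expected[2, 2] = 0.25, 0.5, 0.25
    np.testing.assert_allclose(c.values, expected)


def _random_matrix(rng, n_parent, n_product):
    values = rng.random((n_parent + 1, n_product + 1))
    values *= feasible_mask(n_parent, n_product)
    return TandemerMatrix(values / values.sum())


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.integers(0, 2 ** 32 - 1), st.integers(0, 3), st.integers(0, 3),
       st.integers(0, 3))
def test_cauchy_product_algebra(seed, k1, k2, k3):
    """Commutative, associative (1e-12) and normalization-preserving."""
    rng = np.random.default_rng(seed)
    a = _random_matrix(rng, k1 + int(rng.integers(0, 3)), k1)
    b = _random_matrix(rng, k2 + int(rng.integers(0, 3)), k2)
    c = _random_matrix(rng, k3 + int(rng.integers(0, 3)), k3)
    ab, ba = cauchy_product(a, b), cauchy_product(b, a)
    np.testing.assert_allclose(ab.values, ba.values, atol=1e-12)
    assert abs(ab.values.sum() - 1.0) < 1e-9
    left = cauchy_product(ab, c).values
    right = cauchy_product(a, cauchy_product(b, c)).values
    np.testing.assert_allclose(left, right, atol=1e-12)
    mask = feasible_mask(ab.n_parent, ab.n_product)
    assert np.all(ab.values[~mask] == 0.0)


def test_cauchy_product_warns_on_unnormalized():
    bad = TandemerMatrix(np.array([[0.5]]))
    with pytest.warns(UserWarning):
        cauchy_product(bad, bad)


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.integers(0, 2 ** 32 - 1))
def test_marginals_match_direct_binning(seed):
    """parent/product MIDs equal direct mass-isotopomer binning of the
    isotopomer distribution over the fragment atoms."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 6))
    values = rng.dirichlet(np.ones(1 << n))
    dist = IsotopomerDistribution("X", values)
    parent = sorted(rng.choice(np.arange(1, n + 1),
                               size=int(rng.integers(1, n + 1)), replace=False))
    product = sorted(rng.choice(parent, size=int(rng.integers(0, len(parent) + 1)),
                                replace=False))
    t = tandemer_from_isotopomers(dist, MFP("X", parent, product))
    np.testing.assert_allclose(
        parent_mid(t), direct_fragment_mid(values, n, parent), atol=1e-12)
    np.testing.assert_allclose(
        product_mid(t), direct_fragment_mid(values, n, product), atol=1e-12)
    assert abs(t.values.sum() - 1.0) < 1e-9


def test_parent_mid_of_worked_example():
    t = tandemer_from_isotopomers(WORKED_DIST, WORKED_MFP)
    np.testing.assert_allclose(parent_mid(t), [0.0, 0.6, 0.4, 0.0])
    delta = TandemerMatrix(np.eye(3, 2) * [[1], [0], [0]])
    np.testing.assert_allclose(parent_mid(delta), [1, 0, 0])


def test_clamp_rule():
    clamped = clamp_small_negatives(np.array([-1e-13, 0.5]))
    assert clamped[0] == 0.0 and not np.signbit(clamped[0])
    with pytest.raises(ValidationError):
        clamp_small_negatives(np.array([-1e-9]))


def test_mfp_canonical_identity():
    assert MFP("E", (4, 2, 3, 1), (3, 2)) == MFP("E", (1, 2, 3, 4), (2, 3))
    with pytest.raises(ValidationError):
        MFP("E", (1, 2), (3,))  # product not within parent
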