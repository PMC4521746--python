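"""Cluster system assembly, linear solves, and the full simulation pipeline."""

import numpy as np
import pytest

from tandemer.cluster_solver import (
    assemble_cluster,
    boundary_matrices,
    devectorize,
    simulate_tandemers,
    solve_cluster,
    vectorize,
)
from tandemer.decomposition import cluster_and_sort, identify_mfps
from tandemer.errors import SingularSystemError, ValidationError
from tandemer.iso_core import (
    MFP,
    IsotopomerDistribution,
    TandemerMatrix,
    cauchy_product,
    feasible_mask,
    tandemer_from_isotopomers,
)
from tandemer.model_io import parse_model
from tandemer.oracle import oracle_tandemers

from conftest import make_random_case


def test_vectorize_worked_example():
    mfp = MFP("A", (2, 3, 4), (2, 3))
    values = np.zeros((4, 3))
    values[1, 0], values[2, 1] = 0.6, 0.4
    row = vectorize(TandemerMatrix(values, mfp))
    # feasible order (0,0),(1,0),(1,1),(2,1),(2,2),(3,2)
    np.testing.assert_array_equal(row, [0.0, 0.6, 0.0, 0.4, 0.0, 0.0])
    t = devectorize(row, mfp)
    np.testing.assert_array_equal(t.values, values)


def test_vectorize_round_trip_random():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(0, 5))
        k = int(rng.integers(0, n + 1))
        mfp = MFP("X", range(1, n + 1), range(1, k + 1))
        values = rng.random((n + 1, k + 1)) * feasible_mask(n, k)
        t = TandemerMatrix(values / max(values.sum(), 1e-12), mfp)
        np.testing.assert_array_equal(devectorize(vectorize(t), mfp).values, t.values)
    with pytest.raises(ValidationError):
        devectorize(np.zeros(3), MFP("X", (1, 2), (1,)))


def _toy_cluster_system(toy, product_atom):
    network, fluxes, tracers, targets = toy
    graph = identify_mfps(network, targets)
    clusters = cluster_and_sort(graph)
    known = boundary_matrices(graph, tracers)
    cluster = [c for c in clusters if c[0].product == (product_atom,)][0]
    return graph, known, assemble_cluster(cluster, graph, fluxes, known), fluxes


def test_assemble_toy_first_cluster_structure(toy):
    """The first-cluster flux matrix has the published coefficient structure:
    diagonal -(v1+v5b), -(v2+v3+v4b), -(v2+v4f), -(v5f+v6) over the unknowns
    (B^{3,4}_4, C^{1,2}_2, D^{1,2}_2, E^{3,4}_4), uni-link fluxes off the
    diagonal, and known sources A^{3,4}_4, A^{1,2}_2, A^{3,4}_3 with
    coefficients -v1, -v2, -v2."""
    _graph, _known, system, v = _toy_cluster_system(toy, 4)
    assert system.unknowns == [
        MFP("B", (3, 4), (4,)), MFP("C", (1, 2), (2,)),
        MFP("D", (1, 2), (2,)), MFP("E", (3, 4), (4,)),
    ]
    expected_a = np.array([
        [-(v["v1"] + v["v5_b"]), 0.0, 0.0, v["v5_b"]],
        [v["v3"], -(v["v2"] + v["v3"] + v["v4_b"]), v["v4_b"], 0.0],
        [0.0, v["v4_f"], -(v["v2"] + v["v4_f"]), 0.0],
        [v["v5_f"], v["v6"], 0.0, -(v["v5_f"] + v["v6"])],
    ])
    np.testing.assert_allclose(system.a, expected_a)
    col = {key: c for c, key in enumerate(system.y_keys)}
    expected_b = np.zeros((4, 3))
    expected_b[0, col[("mfp", MFP("A", (3, 4), (4,)))]] = -v["v1"]
    expected_b[1, col[("mfp", MFP("A", (1, 2), (2,)))]] = -v["v2"]
    expected_b[2, col[("mfp", MFP("A", (3, 4), (3,)))]] = -v["v2"]
    np.testing.assert_allclose(system.b, expected_b)
    # flux balance: every row of [A | -B] sums to zero
    np.testing.assert_allclose(system.a.sum(1) - system.b.sum(1), 0.0, atol=1e-12)


def test_assemble_toy_target_cluster_has_cauchy_row(toy):
    """The target cluster's known rows include the condensation source
    [B]^{3,4}_4 (x) [C]^{1,2}_1 with coefficient -v6."""
    network, fluxes, tracers, targets = toy
    graph = identify_mfps(network, targets)
    clusters = cluster_and_sort(graph)
    known = boundary_matrices(graph, tracers)
    cache = {}
    for i, cluster in enumerate(clusters[:-1]):
        known.update(solve_cluster(assemble_cluster(cluster, graph, fluxes, known, i, cache)))
    system = assemble_cluster(clusters[-1], graph, fluxes, known, 2, cache)
    key = ("cauchy", MFP("B", (3, 4), (4,)), MFP("C", (1, 2), (1,)))
    assert key in system.y_keys
    r = system.unknowns.index(MFP("E", (1, 2, 3, 4), (2, 3)))
    assert system.b[r, system.y_keys.index(key)] == -fluxes["v6"]
    expected_row = vectorize(
        cauchy_product(known[key[1]], known[key[2]])
    )
    np.testing.assert_allclose(system.y[system.y_keys.index(key)], expected_row)


def test_solve_toy_rows_sum_to_one(toy):
    _graph, _known, system, _v = _toy_cluster_system(toy, 4)
    solved = solve_cluster(system)
    for t in solved.values():
        assert abs(t.values.sum() - 1.0) < 1e-9


def test_single_mfp_cluster_closed_form():
    """With one unknown fed only by boundary sources, the solution is the
    flux-weighted average of the source matrices."""
    net = parse_model(
        "#media A\nr1: A (ab) -> B (ab)\nr2: A (ab) -> B (ba)\nout: B (ab) ->\n"
    )
    fluxes = {"r1": 2.0, "r2": 1.0, "out": 3.0}
    tracers = {"A": IsotopomerDistribution.from_patterns("A", 2, {"10": 1.0})}
    target = MFP("B", (1, 2), (1,))
    res = simulate_tandemers(net, fluxes, tracers, [target])
    y1 = tandemer_from_isotopomers(tracers["A"], MFP("A", (1, 2), (1,))).values
    y2 = tandemer_from_isotopomers(tracers["A"], MFP("A", (1, 2), (2,))).values
    np.testing.assert_allclose(res[target].values, (2 * y1 + 1 * y2) / 3, atol=1e-12)


def test_simulate_unlabeled_and_fully_labeled(toy):
    network, fluxes, _, targets = toy
    unlabeled = {"A": IsotopomerDistribution.from_patterns("A", 4, {"0000": 1.0})}
    res = simulate_tandemers(network, fluxes, unlabeled, targets, all_mfps=True)
    for t in res.results.values():
        assert t.values[0, 0] == pytest.approx(1.0, abs=1e-12)
    full = {"A": IsotopomerDistribution.from_patterns("A", 4, {"1111": 1.0})}
    res = simulate_tandemers(network, fluxes, full, targets)
    target = targets[0]
    assert res[target].values[4, 2] == pytest.approx(1.0, abs=1e-12)


def test_simulate_matches_oracle_on_toy(toy):
    network, fluxes, tracers, targets = toy
    res = simulate_tandemers(network, fluxes, tracers, targets, all_mfps=True)
    oracle = oracle_tandemers(network, fluxes, tracers, list(res.results), method="both")
    for mfp, t in res.results.items():
        np.testing.assert_allclose(t.values, oracle[mfp].values, atol=1e-8)


def test_flux_scaling_invariance(toy):
    network, fluxes, tracers, targets = toy
    base = simulate_tandemers(network, fluxes, tracers, targets)
    scaled = simulate_tandemers(
        network, {k: 7.5 * v for k, v in fluxes.items()}, tracers, targets
    )
    for t in targets:
        np.testing.assert_allclose(base[t].values, scaled[t].values, atol=1e-12)


def test_linearity_in_a_single_boundary_labeling():
    """The balance system is linear in the labeling of a media metabolite
    that enters each target through at most one substrate slot: mixing its
    tracer mixes the results.  (With condensations joining two descendants of
    the same medium species the response is bilinear, not linear — covered by
    the oracle-equivalence tests.)"""
    net = parse_model(
        "#media A B\nr: A (ab) + B (cd) -> C (abcd)\nout: C (abcd) ->\n"
    )
    fluxes = {"r": 1.0, "out": 1.0}
    targets = [MFP("C", (1, 2, 3, 4), (2, 3))]
    d1 = IsotopomerDistribution.from_patterns("A", 2, {"10": 1.0})
    d2 = IsotopomerDistribution.from_patterns("A", 2, {"01": 1.0})
    b = IsotopomerDistribution.from_patterns("B", 2, {"11": 0.4, "00": 0.6})
    alpha = 0.3
    mix = IsotopomerDistribution("A", alpha * d1.values + (1 - alpha) * d2.values)
    r1 = simulate_tandemers(net, fluxes, {"A": d1, "B": b}, targets)
    r2 = simulate_tandemers(net, fluxes, {"A": d2, "B": b}, targets)
    rm = simulate_tandemers(net, fluxes, {"A": mix, "B": b}, targets)
    for t in targets:
        np.testing.assert_allclose(
            rm[t].values, alpha * r1[t].values + (1 - alpha) * r2[t].values,
            atol=1e-12,
        )


def test_zero_production_is_a_hard_error():
    net = parse_model(
        "#media A\nr1: A (ab) -> B (ab)\nr2: A (ab) -> C (ab)\n"
        "outB: B (ab) ->\noutC: C (ab) ->\n"
    )
    fluxes = {"r1": 1.0, "r2": 0.0, "outB": 1.0, "outC": 0.0}
    tracers = {"A": IsotopomerDistribution.from_patterns("A", 2, {"00": 1.0})}
    with pytest.raises(SingularSystemError, match="C"):
        simulate_tandemers(net, fluxes, tracers, [MFP("C", (1, 2), ())])


def test_unbalanced_fluxes_rejected(toy):
    network, fluxes, tracers, targets = toy
    with pytest.raises(ValidationError, match="steady state"):
        simulate_tandemers(network, dict(fluxes, v1=9.0), tracers, targets)


def test_split_nary_condensation_equals_triple_cauchy_product():
    """A three-way condensation, rewritten to a binary cascade, produces the
    threefold Cauchy product of its media substrates."""
    text = (
        "#media A B C\nv1: A (ab) + B (cd) + C (ef) -> D (abcdef)\n"
        "out: D (abcdef) ->\n"
    )
    net = parse_model(text, split_nary=True)
    fluxes = {r.id: 1.0 for r in net.reactions}
    rng = np.random.default_rng(5)
    tracers = {
        m: IsotopomerDistribution(m, rng.dirichlet(np.ones(4))).validate()
        for m in ("A", "B", "C")
    }
    target = MFP("D", (1, 2, 3, 4, 5, 6), (1, 2))
    res = simulate_tandemers(net, fluxes, tracers, [target])
    ta = tandemer_from_isotopomers(tracers["A"], MFP("A", (1, 2), (1, 2)))
    tb = tandemer_from_isotopomers(tracers["B"], MFP("B", (1, 2), ()))
    tc = tandemer_from_isotopomers(tracers["C"], MFP("C", (1, 2), ()))
    expected = cauchy_product(cauchy_product(ta, tb), tc)
    np.testing.assert_allclose(res[target].values, expected.values, atol=1e-12)


@pytest.mark.parametrize("seed", range(10))
def test_simulate_matches_oracle_on_random_networks(seed):
    """Spot check of the core equivalence property (the acceptance suite runs
    the full 100-network version)."""
    network, fluxes, tracers, targets = make_random_case(seed + 500)
    res = simulate_tandemers(network, fluxes, tracers, targets)
    oracle = oracle_tandemers(network, fluxes, tracers, targets, method="both")
    for t in targets:
        np.testing.assert_allclose(res[t].values, oracle[t].values, atol=1e-8)
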