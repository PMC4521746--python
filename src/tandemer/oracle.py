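"""Brute-force validators over the full isotopomer space.

The tandemer cascade is efficient precisely because it avoids enumerating the
``2^n`` isotopomers of every metabolite.  This module does the opposite, on
purpose: it solves the complete isotopomer balance equations of small networks
by two independent routes — a damped fixed-point iteration directly on
isotopomer fractions, and the cumomer cascade (weight-ordered linear solves on
cumulative labeling probabilities, transformed back to isotopomers) — and
marginalizes the result onto any MFP.  Agreement of the cascade solver with
the tandemer method is the package's core correctness property.

``cumomer_report`` also quantifies what the brute-force baseline would cost:
total cumomer count (= total isotopomer count) and the size of the largest
cumomer cluster.  The cumomer cascade groups its variables by labeling weight,
so cluster sizes here are weight-level counts over the balanced metabolites;
strongly-connected-component sizes are available as an alternative convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import networkx as nx
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import spsolve

from .errors import ConvergenceError, ModelError, ValidationError
from .iso_core import MFP, IsotopomerDistribution, TandemerMatrix, tandemer_from_isotopomers
from .model_io import FluxVector, Network, TracerSpec, total_production_flux

SIZE_GUARD = 1 << 16  # max total isotopomer count handled by brute force
FIXED_POINT_DAMPING = 0.5
FIXED_POINT_TOL = 1e-12
FIXED_POINT_MAX_ITER = 10_000
CROSS_CHECK_TOL = 1e-10


@dataclass
class _Term:
    """One producing-reaction contribution to a metabolite's balance."""

    flux: float
    # per tracked substrate: (metabolite id, [(product atom, substrate atom)])
    parts: list[tuple[str, list[tuple[int, int]]]]


def _production_terms(network: Network, fluxes: FluxVector) -> dict[str, list[_Term]]:
    """All producing-reaction terms per internal tracked metabolite."""
    terms: dict[str, list[_Term]] = {
        m.id: []
        for m in network.metabolites.values()
        if not m.is_media and m.n_atoms > 0
    }
    for r in network.reactions:
        weight = fluxes[r.id] / r.n_alternatives
        for alt in range(r.n_alternatives):
            amap = r.atom_map(alt)
            for p, (met, letters) in enumerate(r.product_alternatives[alt]):
                if met not in terms or not letters:
                    continue
                by_sub: dict[int, list[tuple[int, int]]] = {}
                for atom in range(1, len(letters) + 1):
                    if atom not in amap[p]:
                        raise ModelError(
                            f"atom {atom} of product {met!r} in reaction {r.id!r} "
                            "has no substrate source"
                        )
                    k, pos = amap[p][atom]
                    by_sub.setdefault(k, []).append((atom, pos))
                parts = [
                    (r.substrates[k][0], pairs) for k, pairs in sorted(by_sub.items())
                ]
                terms[met].append(_Term(weight, parts))
    for met, met_terms in terms.items():
        if not met_terms:
            raise ModelError(
                f"internal metabolite {met!r} has no producing reaction"
            )
    return terms


def _partial_index(n_sub: int, n_prod: int, pairs: list[tuple[int, int]]) -> np.ndarray:
    """For each substrate pattern, the product-index bits it contributes."""
    t = np.arange(1 << n_sub, dtype=np.int64)
    idx = np.zeros(1 << n_sub, dtype=np.int64)
    for prod_atom, sub_atom in pairs:
        bit = (t >> (n_sub - sub_atom)) & 1
        idx |= bit << (n_prod - prod_atom)
    return idx


def _term_contribution(
    term: _Term, n_prod: int, x: dict[str, np.ndarray], network: Network
) -> np.ndarray:
    """Flux-weighted isotopomer inflow of one producing term."""
    reduced = []
    for sub_met, pairs in term.parts:
        n_sub = network.metabolites[sub_met].n_atoms
        idx = _partial_index(n_sub, n_prod, pairs)
        reduced.append(np.bincount(idx, weights=x[sub_met], minlength=1 << n_prod))
    if len(reduced) == 1:
        return term.flux * reduced[0]
    r1, r2 = reduced
    out = np.zeros(1 << n_prod)
    support = np.flatnonzero(r1)
    s2 = np.flatnonzero(r2)
    for p1 in support:
        out[p1 | s2] += r1[p1] * r2[s2]
    return term.flux * out


def _media_distributions(network: Network, tracers: TracerSpec) -> dict[str, np.ndarray]:
    x: dict[str, np.ndarray] = {}
    for met in network.metabolites.values():
        if met.is_media and met.n_atoms > 0:
            if met.id not in tracers:
                raise ValidationError(f"no tracer for media metabolite {met.id!r}")
            x[met.id] = tracers[met.id].values
    return x


def _check_size(network: Network, max_size: int) -> None:
    total = sum(
        1 << m.n_atoms
        for m in network.metabolites.values()
        if not m.is_media and m.n_atoms > 0
    )
    if total > max_size:
        raise ValidationError(
            f"network has {total} isotopomers, above the brute-force guard "
            f"({max_size}); use the tandemer solver instead"
        )


def _solve_fixed_point(
    network: Network,
    fluxes: FluxVector,
    tracers: TracerSpec,
    damping: float,
    tol: float,
    max_iter: int,
) -> dict[str, np.ndarray]:
    terms = _production_terms(network, fluxes)
    x = _media_distributions(network, tracers)
    production = {}
    for met in terms:
        production[met] = total_production_flux(network, met, fluxes)
        if production[met] <= 0:
            raise ModelError(f"metabolite {met!r} has zero production flux")
        n = network.metabolites[met].n_atoms
        x[met] = np.zeros(1 << n)
        x[met][0] = 1.0
    for _ in range(max_iter):
        residual = 0.0
        new = {}
        for met, met_terms in terms.items():
            n = network.metabolites[met].n_atoms
            inflow = np.zeros(1 << n)
            for term in met_terms:
                inflow += _term_contribution(term, n, x, network)
            raw = inflow / production[met]
            residual = max(residual, np.abs(inflow - production[met] * x[met]).max())
            new[met] = (1 - damping) * x[met] + damping * raw
        for met in terms:
            x[met] = new[met]
        if residual < tol:
            return x
    raise ConvergenceError(
        f"fixed point not converged after {max_iter} iterations "
        f"(residual {residual:.3e})"
    )


def _superset_sum(x: np.ndarray, n: int) -> np.ndarray:
    """Zeta transform: y[S] = sum over patterns T ⊇ S of x[T]."""
    y = x.copy()
    for b in range(n):
        bit = 1 << b
        idx = np.flatnonzero((np.arange(y.size) & bit) == 0)
        y[idx] += y[idx | bit]
    return y


def _inverse_superset_sum(y: np.ndarray, n: int) -> np.ndarray:
    """Moebius inverse of :func:`_superset_sum`."""
    x = y.copy()
    for b in range(n):
        bit = 1 << b
        idx = np.flatnonzero((np.arange(x.size) & bit) == 0)
        x[idx] -= x[idx | bit]
    return x


def _atoms_to_mask(atoms: list[int], n: int) -> int:
    mask = 0
    for a in atoms:
        mask |= 1 << (n - a)
    return mask


def _solve_cumomer_cascade(
    network: Network, fluxes: FluxVector, tracers: TracerSpec
) -> dict[str, np.ndarray]:
    """Weight-ordered cumomer solve, transformed back to isotopomer space.

    The cumomer of subset S (probability that all atoms of S are labeled)
    obeys a balance whose condensation terms factorize over the two substrate
    parts; terms are linear in same-weight unknowns and constant otherwise, so
    one sparse solve per weight level resolves everything.
    """
    terms = _production_terms(network, fluxes)
    media = _media_distributions(network, tracers)
    cumo: dict[str, np.ndarray] = {}
    for met, dist in media.items():
        cumo[met] = _superset_sum(dist, network.metabolites[met].n_atoms)
    for met in terms:
        n = network.metabolites[met].n_atoms
        cumo[met] = np.zeros(1 << n)
        cumo[met][0] = 1.0  # weight-0 cumomer is identically one

    production = {m: total_production_flux(network, m, fluxes) for m in terms}
    internal = set(terms)
    max_w = max(network.metabolites[m].n_atoms for m in terms)
    for w in range(1, max_w + 1):
        unknowns: list[tuple[str, int]] = []
        for met in sorted(terms):
            n = network.metabolites[met].n_atoms
            for s in range(1 << n):
                if s.bit_count() == w:
                    unknowns.append((met, s))
        if not unknowns:
            continue
        col = {u: c for c, u in enumerate(unknowns)}
        rows, cols, vals = [], [], []
        rhs = np.zeros(len(unknowns))
        for (met, s), r in col.items():
            n = network.metabolites[met].n_atoms
            rows.append(r), cols.append(r), vals.append(-production[met])
            for term in terms[met]:
                sub_masks = []
                for sub_met, pairs in term.parts:
                    n_sub = network.metabolites[sub_met].n_atoms
                    atoms = [
                        sub_atom
                        for prod_atom, sub_atom in pairs
                        if s & (1 << (n - prod_atom))
                    ]
                    mask = _atoms_to_mask(atoms, n_sub)
                    if mask:
                        sub_masks.append((sub_met, mask))
                if len(sub_masks) == 1 and sub_masks[0][0] in internal:
                    sub_met, mask = sub_masks[0]
                    rows.append(r), cols.append(col[(sub_met, mask)])
                    vals.append(term.flux)
                else:  # constant: product of media and/or lower-weight values
                    value = term.flux
                    for sub_met, mask in sub_masks:
                        value *= cumo[sub_met][mask]
                    rhs[r] -= value
        a = coo_matrix((vals, (rows, cols)), shape=(len(unknowns),) * 2).tocsc()
        solution = spsolve(a, rhs) if len(unknowns) > 1 else np.atleast_1d(rhs[0] / a.toarray()[0, 0])
        for (met, s), c in col.items():
            cumo[met][s] = solution[c]

    out = {}
    for met in terms:
        n = network.metabolites[met].n_atoms
        out[met] = _inverse_superset_sum(cumo[met], n)
    return out


def simulate_isotopomers_bruteforce(
    network: Network,
    fluxes: FluxVector,
    tracers: TracerSpec,
    method: str = "fixed_point",
    damping: float = FIXED_POINT_DAMPING,
    tol: float = FIXED_POINT_TOL,
    max_iter: int = FIXED_POINT_MAX_ITER,
    max_size: int = SIZE_GUARD,
) -> dict[str, IsotopomerDistribution]:
    """Full isotopomer distributions of all balanced metabolites.

    ``method`` is one of ``fixed_point`` (damped iteration on the isotopomer
    balances), ``cascade`` (cumomer weight cascade), or ``both`` (run both and
    require agreement below ``1e-10``, returning the fixed-point result).
    """
    missing = {r.id for r in network.reactions} - set(fluxes)
    if missing:
        raise ValidationError(f"missing flux for reactions {sorted(missing)}")
    _check_size(network, max_size)
    if method not in {"fixed_point", "cascade", "both"}:
        raise ValidationError(f"unknown method {method!r}")
    x = cascade = None
    if method in {"fixed_point", "both"}:
        x = _solve_fixed_point(network, fluxes, tracers, damping, tol, max_iter)
    if method in {"cascade", "both"}:
        cascade = _solve_cumomer_cascade(network, fluxes, tracers)
    if method == "both":
        for met in cascade:
            dev = np.abs(x[met] - cascade[met]).max()
            if dev > CROSS_CHECK_TOL:
                raise ConvergenceError(
                    f"fixed-point and cumomer-cascade solvers disagree on "
                    f"{met!r} by {dev:.3e}"
                )
    chosen = x if x is not None else cascade
    out = {}
    for met_id, values in chosen.items():
        if not network.metabolites[met_id].is_media:
            out[met_id] = IsotopomerDistribution(met_id, values).validate()
    return out


def oracle_tandemers(
    network: Network,
    fluxes: FluxVector,
    tracers: TracerSpec,
    targets: list[MFP],
    method: str = "fixed_point",
    **kwargs,
) -> dict[MFP, TandemerMatrix]:
    """Tandemer matrices obtained by brute force + marginalization."""
    dists = simulate_isotopomers_bruteforce(network, fluxes, tracers, method, **kwargs)
    out = {}
    for t in targets:
        if network.metabolite(t.metabolite).is_media:
            dist = tracers[t.metabolite]
        else:
            dist = dists[t.metabolite]
        out[t] = tandemer_from_isotopomers(dist, t)
    return out


@dataclass
class CumomerReport:
    """Size of the cumomer (full isotopomer) model of a network.

    ``total`` counts every cumomer of every tracked metabolite, media
    included (their labeling is an input, but their cumomers are part of the
    isotopomer model).  ``cluster_sizes`` follows the cascade convention:
    cumomers of the balanced metabolites grouped by labeling weight, weight-0
    excluded.  ``scc_cluster_sizes`` (optional) instead reports strongly
    connected components of the cumomer dependency graph.
    """

    total: int
    cluster_sizes: dict[int, int]
    max_cluster_size: int
    convention: str = "weight-level, balanced metabolites, weight >= 1"
    scc_cluster_sizes: list[int] | None = None

    def to_dict(self) -> dict:
        return {
            "total_cumomers": self.total,
            "cluster_sizes": self.cluster_sizes,
            "max_cluster_size": self.max_cluster_size,
            "convention": self.convention,
            "scc_cluster_sizes": self.scc_cluster_sizes,
        }


def cumomer_report(
    network: Network, targets: list[MFP] | None = None, compute_scc: bool = False
) -> CumomerReport:
    """Count the cumomer variables a full isotopomer model would need.

    The cumomer approach simulates every metabolite regardless of which
    targets are requested, so ``targets`` does not affect the counts.
    """
    del targets  # the cumomer model is target-independent
    total = sum(
        1 << m.n_atoms for m in network.metabolites.values() if m.n_atoms > 0
    )
    internal = [
        m for m in network.metabolites.values() if not m.is_media and m.n_atoms > 0
    ]
    sizes: dict[int, int] = {}
    for w in range(1, max((m.n_atoms for m in internal), default=0) + 1):
        count = sum(comb(m.n_atoms, w) for m in internal)
        if count:
            sizes[w] = count
    scc_sizes = None
    if compute_scc:
        scc_sizes = _cumomer_scc_sizes(network)
    return CumomerReport(
        total=total,
        cluster_sizes=sizes,
        max_cluster_size=max(sizes.values(), default=0),
        scc_cluster_sizes=scc_sizes,
    )


def _cumomer_scc_sizes(network: Network) -> list[int]:
    """SCC sizes of the weight->=1 cumomer dependency graph (alternative
    clustering convention; tractable for small networks only)."""
    unit_fluxes = {r.id: 1.0 for r in network.reactions}
    terms = _production_terms(network, unit_fluxes)
    g = nx.DiGraph()
    for met in terms:
        n = network.metabolites[met].n_atoms
        for s in range(1, 1 << n):
            g.add_node((met, s))
            for term in terms[met]:
                for sub_met, pairs in term.parts:
                    n_sub = network.metabolites[sub_met].n_atoms
                    atoms = [
                        sub_atom
                        for prod_atom, sub_atom in pairs
                        if s & (1 << (n - prod_atom))
                    ]
                    mask = _atoms_to_mask(atoms, n_sub)
                    if mask and sub_met in terms:
                        g.add_edge((sub_met, mask), (met, s))
    return sorted((len(c) for c in nx.strongly_connected_components(g)), reverse=True)
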