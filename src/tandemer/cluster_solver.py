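"""Assembly and sequential solution of per-cluster balance systems.

At isotopic steady state every internal MFP obeys a flux balance: its tandemer
matrix, weighted by total production flux, equals the flux-weighted sum of the
matrices of its substrate MFPs (Cauchy products for condensations).  Within
one cluster (a strongly connected component of the MFP graph) these balances
are linear in the unknown matrices, because condensation sources always sit in
strictly earlier clusters.  Each cluster therefore yields one linear system

    A_i X_i = B_i Y_i

with X_i rows the vectorized unknown tandemer distributions (infeasible
entries removed), Y_i rows the known distributions and Cauchy products from
boundary/earlier clusters, A_i carrying a negative total-production diagonal
and positive intra-cluster fluxes, and B_i negative fluxes to known sources.
Solving the clusters in topological order yields every requested distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import LinearOperator, onenormest, splu

from .decomposition import MFPGraph, cluster_and_sort, identify_mfps
from .errors import NumericalError, SingularSystemError, ValidationError
from .iso_core import (
    MFP,
    TandemerMatrix,
    cauchy_product,
    feasible_mask,
    n_feasible,
    tandemer_from_isotopomers,
)
from .model_io import (
    FluxVector,
    Network,
    TracerSpec,
    check_steady_state,
    model_hash,
    total_production_flux,
)

CONDITION_LIMIT = 1e12
_DENSE_LIMIT = 400  # clusters above this size go through sparse LU


def vectorize(t: TandemerMatrix) -> np.ndarray:
    """Row vector of the feasible entries, ordered (i ascending, j ascending)."""
    mask = feasible_mask(t.n_parent, t.n_product)
    return t.values[mask]


def devectorize(row: np.ndarray, mfp: MFP) -> TandemerMatrix:
    """Restore the full matrix (infeasible zeros) from a feasible-entry row."""
    row = np.asarray(row, dtype=float)
    if row.size != n_feasible(mfp.n_parent, mfp.n_product):
        raise ValidationError(
            f"row of length {row.size} does not match {mfp} "
            f"({n_feasible(mfp.n_parent, mfp.n_product)} feasible tandemers)"
        )
    values = np.zeros(mfp.shape)
    values[feasible_mask(mfp.n_parent, mfp.n_product)] = row
    return TandemerMatrix(values, mfp)


@dataclass
class ClusterSystem:
    """The assembled linear system of one cluster."""

    index: int
    unknowns: list[MFP]
    a: np.ndarray  # (n, n), negative diagonal
    b: np.ndarray  # (n, n_known), non-positive entries
    y: np.ndarray  # (n_known, width) vectorized known rows
    y_keys: list[tuple]  # provenance of each Y row
    condition: float = np.nan


@dataclass
class SimulationResult:
    """Tandemer matrices for the requested (or all) MFPs, with provenance."""

    results: dict[MFP, TandemerMatrix]
    graph: MFPGraph
    provenance: dict = field(default_factory=dict)

    def __getitem__(self, mfp: MFP) -> TandemerMatrix:
        return self.results[mfp]


def assemble_cluster(
    cluster: list[MFP],
    graph: MFPGraph,
    fluxes: FluxVector,
    known: dict[MFP, TandemerMatrix],
    index: int = 0,
    cauchy_cache: dict | None = None,
) -> ClusterSystem:
    """Build ``A_i X_i = B_i Y_i`` for one cluster.

    Sign convention: the diagonal of ``A_i`` is minus the total production
    flux of the unknown's metabolite, intra-cluster uni-substrate links enter
    ``A_i`` with ``+v``, and known sources enter ``B_i`` with ``-v``, so each
    row of the stacked ``[A_i | B_i]`` sums to zero by flux balance.  Cauchy
    products of known condensation sources are computed once per distinct
    source pair and appended as Y rows.
    """
    if cauchy_cache is None:
        cauchy_cache = {}
    unknowns = sorted(cluster)
    pos = {m: r for r, m in enumerate(unknowns)}
    n = len(unknowns)
    shape = unknowns[0].shape
    width = n_feasible(unknowns[0].n_parent, unknowns[0].n_product)

    a = np.zeros((n, n))
    b_cols: dict[tuple, int] = {}
    y_rows: list[np.ndarray] = []
    b_entries: list[tuple[int, int, float]] = []

    def y_col(key, matrix: TandemerMatrix) -> int:
        if key not in b_cols:
            row = vectorize(matrix)
            if row.size != width:
                raise NumericalError(f"known row {key} has width {row.size}, expected {width}")
            b_cols[key] = len(y_rows)
            y_rows.append(row)
        return b_cols[key]

    for r, mfp in enumerate(unknowns):
        production = total_production_flux(graph.network, mfp.metabolite, fluxes)
        if production <= 0.0:
            raise SingularSystemError(
                f"metabolite {mfp.metabolite!r} has zero total production flux; "
                f"its labeling is undefined at steady state (needed for {mfp})"
            )
        a[r, r] -= production
        for link in graph.edges[mfp]:
            v = fluxes[link.reaction_id] * link.weight
            if v == 0.0:
                continue
            if link.kind == "uni":
                (src,) = link.sources
                if src in pos:
                    a[r, pos[src]] += v
                else:
                    c = y_col(("mfp", src), known[src])
                    b_entries.append((r, c, -v))
            else:
                s1, s2 = link.sources
                key = ("cauchy", s1, s2)
                if key not in cauchy_cache:
                    try:
                        cauchy_cache[key] = cauchy_product(known[s1], known[s2], mfp)
                    except KeyError as exc:
                        raise NumericalError(
                            f"source {exc} of {mfp} not yet solved: cluster ordering bug"
                        ) from exc
                c = y_col(key, cauchy_cache[key])
                b_entries.append((r, c, -v))

    b = np.zeros((n, len(y_rows)))
    for r, c, v in b_entries:
        b[r, c] += v
    y = np.vstack(y_rows) if y_rows else np.zeros((0, width))
    return ClusterSystem(index, unknowns, a, b, y, list(b_cols))


def solve_cluster(system: ClusterSystem) -> dict[MFP, TandemerMatrix]:
    """Solve one cluster system by (sparse) LU; never forms an inverse.

    Every returned row is clamped by the small-negative rule and must sum to
    one up to tolerance — conservation holds by construction, so a violation
    signals a numerical failure and raises.
    """
    rhs = system.b @ system.y
    n = system.a.shape[0]
    if n <= _DENSE_LIMIT:
        cond = np.linalg.cond(system.a, 1)
        if not np.isfinite(cond) or cond > CONDITION_LIMIT:
            raise SingularSystemError(
                f"cluster {system.index} is singular or ill-conditioned "
                f"(cond~{cond:.2e}); MFPs: {system.unknowns}"
            )
        x = np.linalg.solve(system.a, rhs)
    else:
        sparse_a = csc_matrix(system.a)
        try:
            lu = splu(sparse_a)
        except RuntimeError as exc:
            raise SingularSystemError(
                f"cluster {system.index} is singular; MFPs: {system.unknowns}"
            ) from exc
        inv_norm = onenormest(
            LinearOperator(system.a.shape, matvec=lu.solve)
        )
        cond = inv_norm * np.abs(system.a).sum(axis=0).max()
        if cond > CONDITION_LIMIT:
            raise SingularSystemError(
                f"cluster {system.index} is numerically rank deficient "
                f"(cond~{cond:.2e}); MFPs: {system.unknowns}"
            )
        x = lu.solve(rhs)
    system.condition = float(cond)

    out: dict[MFP, TandemerMatrix] = {}
    for r, mfp in enumerate(system.unknowns):
        try:
            out[mfp] = devectorize(x[r], mfp).validate()
        except ValidationError as exc:
            raise NumericalError(f"solved row for {mfp} invalid: {exc}") from exc
    return out


def boundary_matrices(
    graph: MFPGraph, tracers: TracerSpec
) -> dict[MFP, TandemerMatrix]:
    """Tandemer matrices of media-metabolite MFPs from the tracer spec."""
    known: dict[MFP, TandemerMatrix] = {}
    for mfp in graph.boundary:
        if mfp.metabolite not in tracers:
            raise ValidationError(
                f"media metabolite {mfp.metabolite!r} is needed (MFP {mfp}) but "
                "has no tracer entry"
            )
        known[mfp] = tandemer_from_isotopomers(tracers[mfp.metabolite], mfp)
    return known


def simulate_tandemers(
    network: Network,
    fluxes: FluxVector,
    tracers: TracerSpec,
    targets: list[MFP],
    all_mfps: bool = False,
    steady_state_tol: float = 1e-6,
) -> SimulationResult:
    """Simulate the tandemer distributions of the target MFPs.

    Runs the full pipeline: steady-state check, MFP identification, SCC
    clustering with topological ordering, boundary matrices from tracers, then
    one linear solve per cluster in cascade order.  With ``all_mfps`` the
    result carries every internal MFP, not just the targets.
    """
    missing = {r.id for r in network.reactions} - set(fluxes)
    if missing:
        raise ValidationError(f"missing flux for reactions {sorted(missing)}")
    report = check_steady_state(network, fluxes, tol=steady_state_tol)
    if not report.ok:
        raise ValidationError(
            f"flux vector violates steady state for metabolites {report.failing()}"
        )
    graph = identify_mfps(network, targets)
    clusters = cluster_and_sort(graph)
    known = boundary_matrices(graph, tracers)

    cauchy_cache: dict = {}
    diagnostics = []
    for i, cluster in enumerate(clusters):
        system = assemble_cluster(cluster, graph, fluxes, known, i, cauchy_cache)
        known.update(solve_cluster(system))
        diagnostics.append(
            {"cluster": i, "size": len(cluster), "condition": system.condition}
        )

    wanted = list(known) if all_mfps else targets
    results = {}
    for t in wanted:
        if t not in known:
            raise ValidationError(f"target {t} unreachable in the MFP closure")
        results[t] = known[t]
    flux_hash = str(hash(tuple(sorted(fluxes.items()))))
    return SimulationResult(
        results,
        graph,
        provenance={
            "model_hash": model_hash(network),
            "flux_hash": flux_hash,
            "n_clusters": len(clusters),
            "cluster_diagnostics": diagnostics,
        },
    )
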