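"""Minimal-MFP identification and cluster ordering.

Simulating the tandemer distribution of a target fragment pair does not
require the full isotopomer state of the network.  Pulling the parent and
product fragments back through each producing reaction's atom map yields the
*substrate MFPs* whose distributions suffice: in a uni-substrate reaction the
product matrix simply equals the substrate matrix (fragment sizes preserved),
while a condensation splits the fragments across its two substrates and
combines their matrices by Cauchy product.  Iterating this pullback from the
requested targets until closure gives the minimal variable set, in the same
spirit as the elementary-metabolite-unit (EMU) decomposition of
mass-isotopomer simulation.

Because uni-substrate pullback preserves the parent fragment size and
condensation strictly reduces it on both sides, the dependency graph of MFPs
decomposes into strongly connected components that can be topologically
ordered into a cascade of clusters of non-decreasing parent size, each
solvable as one linear system given its predecessors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .errors import ModelError, ValidationError
from .iso_core import MFP
from .model_io import Network, Reaction


@dataclass(frozen=True)
class SubstrateLink:
    """One producing-reaction term in the balance of a target MFP.

    ``sources`` holds one MFP for a uni-substrate term or two (ordered by
    substrate position) for a condensation term; ``weight`` is the fraction of
    the reaction flux carried by this atom-mapping alternative.
    """

    reaction_id: str
    kind: str  # "uni" | "bi"
    sources: tuple[MFP, ...]
    weight: float = 1.0
    product_instance: int = 0
    alternative: int = 0


def substrate_mfps(mfp: MFP, reaction: Reaction, network: Network) -> list[SubstrateLink]:
    """Pull an MFP back through one reaction's atom map(s).

    Returns one link per product instance of ``mfp.metabolite`` and per
    mapping alternative.  A condensation in which one substrate receives no
    parent atoms degrades to a uni-substrate link on the other.
    """
    links: list[SubstrateLink] = []
    weight = 1.0 / reaction.n_alternatives
    for alt in range(reaction.n_alternatives):
        amap = reaction.atom_map(alt)
        for p, (met, _letters) in enumerate(reaction.product_alternatives[alt]):
            if met != mfp.metabolite:
                continue
            parent_by_sub: dict[int, list[int]] = {}
            product_by_sub: dict[int, list[int]] = {}
            for a in mfp.parent:
                try:
                    k, pos = amap[p][a]
                except KeyError:
                    raise ModelError(
                        f"{mfp}: atom {a} of {met!r} has no substrate source in "
                        f"reaction {reaction.id!r}; untracked influx atoms must "
                        "come from a declared media metabolite"
                    ) from None
                parent_by_sub.setdefault(k, []).append(pos)
                if a in mfp.product:
                    product_by_sub.setdefault(k, []).append(pos)
            sources = tuple(
                MFP(
                    reaction.substrates[k][0],
                    parent_by_sub[k],
                    product_by_sub.get(k, ()),
                )
                for k in sorted(parent_by_sub)
            )
            kind = "bi" if len(sources) == 2 else "uni"
            links.append(SubstrateLink(reaction.id, kind, sources, weight, p, alt))
    if not links:
        raise ModelError(f"reaction {reaction.id!r} does not produce {mfp.metabolite!r}")
    return links


@dataclass
class MFPGraph:
    """Dependency graph of MFPs with ordered solution clusters.

    ``nodes`` are the internal (balanced) MFPs, ``boundary`` the MFPs of media
    metabolites whose matrices come straight from the tracer specification.
    ``edges[target]`` lists every producing-reaction link of ``target``.
    ``clusters`` is filled by :func:`cluster_and_sort`.
    """

    network: Network
    targets: list[MFP]
    nodes: list[MFP] = field(default_factory=list)
    boundary: list[MFP] = field(default_factory=list)
    edges: dict[MFP, list[SubstrateLink]] = field(default_factory=dict)
    clusters: list[list[MFP]] = field(default_factory=list)


def identify_mfps(network: Network, targets: list[MFP]) -> MFPGraph:
    """Closure of the targets under substrate pullback (recursive traversal).

    Starting from the target list, substrate MFPs are iteratively added for
    every producing reaction until no new MFP appears.  MFPs of media
    metabolites terminate the recursion as boundary nodes.
    """
    graph = MFPGraph(network, list(targets))
    internal: set[MFP] = set()
    boundary: set[MFP] = set()
    producers_cache: dict[str, list[Reaction]] = {}

    def producers_of(met_id: str) -> list[Reaction]:
        if met_id not in producers_cache:
            seen = []
            for r in network.reactions:
                if any(m == met_id for m, _l in r.products) and r not in seen:
                    seen.append(r)
            producers_cache[met_id] = seen
        return producers_cache[met_id]

    queue: list[MFP] = []
    for t in targets:
        met = network.metabolite(t.metabolite)
        if any(a > met.n_atoms for a in t.parent):
            raise ValidationError(f"target {t}: atom index beyond {met.n_atoms} atoms")
        if not t.parent:
            raise ValidationError(f"target {t}: empty parent fragment")
        if met.is_media:
            boundary.add(t)
        elif t not in internal:
            internal.add(t)
            queue.append(t)

    while queue:
        mfp = queue.pop()
        rxns = producers_of(mfp.metabolite)
        if not rxns:
            raise ModelError(
                f"{mfp}: metabolite {mfp.metabolite!r} has no producing reaction "
                "and is not a media metabolite"
            )
        links: list[SubstrateLink] = []
        for r in rxns:
            links.extend(substrate_mfps(mfp, r, network))
        graph.edges[mfp] = links
        for link in links:
            for src in link.sources:
                if network.metabolite(src.metabolite).is_media:
                    boundary.add(src)
                elif src not in internal:
                    internal.add(src)
                    queue.append(src)

    graph.nodes = sorted(internal)
    graph.boundary = sorted(boundary)
    return graph


def cluster_and_sort(graph: MFPGraph) -> list[list[MFP]]:
    """Strongly connected components of the internal subgraph, in a
    deterministic topological order (non-decreasing parent size, ties broken
    by the smallest canonical MFP name)."""
    dg = nx.DiGraph()
    dg.add_nodes_from(graph.nodes)
    internal = set(graph.nodes)
    for target, links in graph.edges.items():
        for link in links:
            for src in link.sources:
                if src in internal:
                    dg.add_edge(src, target)
    cond = nx.condensation(dg)
    order = nx.lexicographical_topological_sort(
        cond,
        key=lambda c: (
            min(m.n_parent for m in cond.nodes[c]["members"]),
            repr(min(cond.nodes[c]["members"])),
        ),
    )
    clusters = [sorted(cond.nodes[c]["members"]) for c in order]
    for cluster in clusters:
        sizes = {(m.n_parent, m.n_product) for m in cluster}
        if len(sizes) != 1:
            raise ModelError(
                f"cluster {cluster} mixes fragment sizes {sizes}; "
                "inconsistent atom mappings"
            )
    graph.clusters = clusters
    return clusters


@dataclass
class DecompositionStats:
    """Counts summarizing a clustered MFP graph."""

    n_internal: int
    n_boundary: int
    n_total: int
    n_clusters: int
    cluster_sizes: list[int]
    max_cluster_size: int
    per_metabolite: dict[str, int]
    bound_ok: bool  # every per-metabolite count < 3^n

    def to_dict(self) -> dict:
        return {
            "mfp_count": self.n_internal,
            "boundary_count": self.n_boundary,
            "total_mfp_count": self.n_total,
            "n_clusters": self.n_clusters,
            "cluster_sizes": self.cluster_sizes,
            "max_cluster_size": self.max_cluster_size,
            "per_metabolite": self.per_metabolite,
            "bound_ok": self.bound_ok,
        }


def decomposition_stats(graph: MFPGraph) -> DecompositionStats:
    """Variable counts, cluster sizes and the 3^n per-metabolite bound check."""
    if not graph.clusters:
        cluster_and_sort(graph)
    per_met: dict[str, int] = {}
    for mfp in (*graph.nodes, *graph.boundary):
        per_met[mfp.metabolite] = per_met.get(mfp.metabolite, 0) + 1
    bound_ok = all(
        count < 3 ** graph.network.metabolite(met).n_atoms
        for met, count in per_met.items()
    )
    sizes = [len(c) for c in graph.clusters]
    return DecompositionStats(
        n_internal=len(graph.nodes),
        n_boundary=len(graph.boundary),
        n_total=len(graph.nodes) + len(graph.boundary),
        n_clusters=len(sizes),
        cluster_sizes=sizes,
        max_cluster_size=max(sizes, default=0),
        per_metabolite=dict(sorted(per_met.items())),
        bound_ok=bound_ok,
    )
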