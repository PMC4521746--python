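"""Shipped network models and random-network generators.

Two curated models are bundled as text constants (mirrored under
``fixtures/`` in the repository):

* a five-metabolite toy network (A supplied in the media; B, C, D, E
  balanced) whose atom maps were reconstructed so that every cluster balance
  equation of the worked example — including the cluster-(I) flux matrix and
  the condensation term ``[B]^{3,4}_4 ⊗ [C]^{1,2}_1 · v6`` — comes out
  exactly;

* a lumped model of mammalian methionine metabolism (transmethylation cycle,
  polyamine branch, methionine salvage).  Balanced species: methionine (5
  carbons), S-adenosylmethionine (SAM, 15), S-adenosylhomocysteine (SAH, 14),
  methylthioadenosine (MTA, 11) and homocysteine (4).  Media species with
  externally known labeling: medium methionine (5), ATP as the adenosyl donor
  (10) and the methyl group of 5-methyl-tetrahydrofolate (1).  The salvage
  atom map follows the known chemistry: ribose C-1' is lost as formate,
  C-2'..C-5' become methionine C-1..C-4 and the S-methyl group is retained.
  The default target set takes intact metabolites as parent fragments, the
  adenine group as product fragment for SAM/SAH/MTA and the four non-methyl
  carbons for methionine/homocysteine.

The random generator builds atom-conserving networks (uni transfers and
binary condensations, optional reversible pair for cycles) that always admit
a strictly positive steady-state flux vector, for property-based validation
against the brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .errors import TandemerError
from .iso_core import MFP, IsotopomerDistribution
from .model_io import (
    FluxVector,
    Network,
    TracerSpec,
    parse_fluxes,
    parse_model,
    parse_targets,
    parse_tracers,
)

TOY_MODEL = """\
# Toy network: media metabolite A (4 carbons) feeds B, C, D, E.
# v2 splits A into two 2-carbon halves (the D half written reversed);
# v3 transfers the B 3,4-carbon unit onto C; v6 condenses that unit with C.
#media A
v1: A (abcd) -> B (abcd)
v2: A (abcd) -> C (ab) + D (dc)
v3: B (abcd) -> C (cd)
v4: C (ab) <-> D (ab)
v5: B (abcd) <-> E (abcd)
v6: B (abcd) + C (ef) -> E (cdef)
e_C: C (ab) ->
e_D: D (ab) ->
e_E: E (abcd) ->
"""

TOY_FLUXES = """\
reaction,flux
v1,3.0
v2,1.0
v3,1.0
v4_f,0.5
v4_b,0.5
v5_f,2.0
v5_b,1.0
v6,1.0
e_C,1.0
e_D,1.0
e_E,2.0
"""

TOY_TRACERS = """\
metabolite,isotopomer,fraction
A,1100,0.5
A,0000,0.5
"""

TOY_TARGETS = """\
metabolite,parent_atoms,product_atoms
E,"1,2,3,4","2,3"
"""

# Methionine numbering: Met 1-4 backbone (1 = carboxyl), 5 = S-methyl.
# SAM = Met 1-5 + adenosyl 6-15 (adenine 6-10, ribose 11-15, C-1'..C-5').
# SAH drops the methyl; MTA = methyl + adenosyl (adenine 2-6, ribose 7-11).
# ATP contributes its 10 adenosyl carbons (adenine 1-5, ribose 6-10).
METHIONINE_MODEL = """\
#media Met_media ATP CH3_THF
upt: Met_media (abcde) -> Met (abcde)
mat: Met (abcde) + ATP (fghijklmno) -> SAM (abcdefghijklmno)
mt: SAM (abcdefghijklmno) -> SAH (abcdfghijklmno)
sahh: SAH (abcdefghijklmn) -> HCys (abcd)
ms: HCys (abcd) + CH3_THF (e) -> Met (abcde)
poly: SAM (abcdefghijklmno) -> MTA (efghijklmno)
salv: MTA (abcdefghijk) -> Met (hijka)
prot: Met (abcde) ->
ts: HCys (abcd) ->
"""

METHIONINE_FLUXES = """\
reaction,flux
upt,3.0
mat,10.0
mt,7.0
sahh,7.0
ms,5.0
poly,3.0
salv,3.0
prot,1.0
ts,2.0
"""

# default study condition: 50% U-13C5 medium methionine, unlabeled cofactors
METHIONINE_TRACERS = """\
metabolite,isotopomer,fraction
Met_media,11111,0.5
Met_media,00000,0.5
ATP,0000000000,1.0
CH3_THF,0,1.0
"""

METHIONINE_TARGETS = """\
metabolite,parent_atoms,product_atoms
Met,"1,2,3,4,5","1,2,3,4"
SAM,"1,2,3,4,5,6,7,8,9,10,11,12,13,14,15","6,7,8,9,10"
SAH,"1,2,3,4,5,6,7,8,9,10,11,12,13,14","5,6,7,8,9"
MTA,"1,2,3,4,5,6,7,8,9,10,11","2,3,4,5,6"
HCys,"1,2,3,4","1,2,3,4"
"""

FIXTURE_FILES = {
    "toy_model.txt": TOY_MODEL,
    "toy_fluxes.csv": TOY_FLUXES,
    "toy_tracers.csv": TOY_TRACERS,
    "toy_targets.csv": TOY_TARGETS,
    "methionine_model.txt": METHIONINE_MODEL,
    "methionine_fluxes.csv": METHIONINE_FLUXES,
    "methionine_tracers.csv": METHIONINE_TRACERS,
    "methionine_targets.csv": METHIONINE_TARGETS,
}


def toy_network() -> tuple[Network, FluxVector, TracerSpec, list[MFP]]:
    """The worked-example toy network with its flux vector, tracer and target."""
    network = parse_model(TOY_MODEL)
    fluxes = parse_fluxes(TOY_FLUXES, network)
    tracers = parse_tracers(TOY_TRACERS, network)
    targets = parse_targets(TOY_TARGETS, network)
    return network, fluxes, tracers, targets


def methionine_network() -> tuple[Network, list[MFP]]:
    """The methionine metabolism model with its default MS/MS target set."""
    network = parse_model(METHIONINE_MODEL)
    targets = parse_targets(METHIONINE_TARGETS, network)
    return network, targets


def methionine_fluxes(network: Network | None = None) -> FluxVector:
    if network is None:
        network = parse_model(METHIONINE_MODEL)
    return parse_fluxes(METHIONINE_FLUXES, network)


def methionine_tracers(network: Network | None = None) -> TracerSpec:
    if network is None:
        network = parse_model(METHIONINE_MODEL)
    return parse_tracers(METHIONINE_TRACERS, network)


@dataclass
class RandomNetworkParams:
    """Knobs of the random atom-mapped network generator."""

    n_metabolites: int = 6
    max_atoms: int = 4
    n_reactions: int = 8
    bi_substrate_fraction: float = 0.4
    cycle_enforcement: bool = True
    seed: int = 0
    max_retries: int = 20


_LETTERS = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"


def random_network(params: RandomNetworkParams) -> Network:
    """A seeded random network that parses, conserves atoms and admits a
    strictly positive steady-state flux vector (checked by construction)."""
    rng = np.random.default_rng(params.seed)
    for _attempt in range(params.max_retries):
        text = _random_network_text(rng, params)
        network = parse_model(text)
        try:
            random_fluxes(network, seed=int(rng.integers(1 << 30)))
        except TandemerError:
            continue
        return network
    raise TandemerError(
        f"could not generate a feasible network after {params.max_retries} tries"
    )


def _random_network_text(rng, params: RandomNetworkParams) -> str:
    n_int = max(2, params.n_metabolites - 1)
    atoms = {"S0": params.max_atoms}
    for k in range(n_int):
        atoms[f"M{k}"] = int(rng.integers(1, params.max_atoms + 1))
    internal = [f"M{k}" for k in range(n_int)]
    lines = ["#media S0"]
    counter = 0

    def add_reaction(subs: list[str], prod: str) -> None:
        nonlocal counter
        n_prod = atoms[prod]
        # distribute product atoms over the substrates (each side non-empty
        # when binary), then assign letters
        if len(subs) == 1:
            split = [n_prod]
        else:
            lo = max(1, n_prod - atoms[subs[1]])
            hi = min(atoms[subs[0]], n_prod - 1)
            take = int(rng.integers(lo, hi + 1))
            split = [take, n_prod - take]
        pool = iter(_LETTERS)
        sub_terms, prod_letters = [], [""] * n_prod
        positions = list(rng.permutation(n_prod))
        start = 0
        for sub, k in zip(subs, split):
            mine = positions[start:start + k]
            start += k
            letters = []
            slots = sorted(rng.choice(atoms[sub], size=k, replace=False).tolist())
            assigned = {}
            for slot, p in zip(slots, sorted(mine)):
                assigned[slot] = p
            for slot in range(atoms[sub]):
                letter = next(pool)
                letters.append(letter)
                if slot in assigned:
                    prod_letters[assigned[slot]] = letter
            sub_terms.append(f"{sub} ({''.join(letters)})")
        counter += 1
        lines.append(
            f"r{counter}: {' + '.join(sub_terms)} -> {prod}"
            f" ({''.join(prod_letters)})"
        )

    # guarantee a producer for every internal metabolite using earlier species
    for k, met in enumerate(internal):
        earlier = ["S0"] + internal[:k]
        use_bi = (
            rng.random() < params.bi_substrate_fraction
            and any(atoms[e1] + atoms[e2] >= atoms[met]
                    for e1 in earlier for e2 in earlier
                    if atoms[e1] < atoms[met] and atoms[e2] < atoms[met])
        )
        if use_bi:
            pairs = [
                (e1, e2)
                for e1 in earlier
                for e2 in earlier
                if atoms[e1] < atoms[met] and atoms[e2] < atoms[met]
                and atoms[e1] + atoms[e2] >= atoms[met]
            ]
            e1, e2 = pairs[int(rng.integers(len(pairs)))]
            add_reaction([e1, e2], met)
        else:
            donors = [e for e in earlier if atoms[e] >= atoms[met]]
            if donors:
                add_reaction([donors[int(rng.integers(len(donors)))]], met)
            else:
                pairs = [
                    (e1, e2)
                    for e1 in earlier
                    for e2 in earlier
                    if 0 < atoms[e1] < atoms[met]
                    and 0 < atoms[e2] < atoms[met]
                    and atoms[e1] + atoms[e2] >= atoms[met]
                ]
                if not pairs:
                    add_reaction(["S0"], met)  # max_atoms source always fits
                else:
                    e1, e2 = pairs[int(rng.integers(len(pairs)))]
                    add_reaction([e1, e2], met)

    # extra random reactions, including back edges (cycles)
    extra = max(0, params.n_reactions - n_int)
    for _ in range(extra):
        prod = internal[int(rng.integers(n_int))]
        if rng.random() < params.bi_substrate_fraction:
            pairs = [
                (e1, e2)
                for e1 in internal + ["S0"]
                for e2 in internal + ["S0"]
                if atoms[e1] < atoms[prod] and atoms[e2] < atoms[prod]
                and atoms[e1] + atoms[e2] >= atoms[prod]
                and e1 != prod and e2 != prod
            ]
            if pairs:
                e1, e2 = pairs[int(rng.integers(len(pairs)))]
                add_reaction([e1, e2], prod)
                continue
        donors = [e for e in internal + ["S0"] if atoms[e] >= atoms[prod] and e != prod]
        if donors:
            add_reaction([donors[int(rng.integers(len(donors)))]], prod)

    if params.cycle_enforcement:
        # a reversible identity exchange between two equal-size metabolites
        sizes: dict[int, list[str]] = {}
        for met in internal:
            sizes.setdefault(atoms[met], []).append(met)
        for mets in sizes.values():
            if len(mets) >= 2:
                m1, m2 = mets[0], mets[1]
                letters = _LETTERS[: atoms[m1]]
                counter += 1
                lines.append(f"r{counter}: {m1} ({letters}) <-> {m2} ({letters})")
                break

    for met in internal:
        lines.append(f"out_{met}: {met} ({_LETTERS[: atoms[met]]}) ->")
    return "\n".join(lines) + "\n"


def random_fluxes(network: Network, seed: int = 0) -> FluxVector:
    """A strictly positive steady-state flux vector, sampled reproducibly.

    Finds a vertex of the flux polytope {v : S v = 0, lb <= v <= ub} for a
    random linear objective; the lower bound keeps every reaction active.
    """
    rng = np.random.default_rng(seed)
    reactions = network.reactions
    internal = [
        m.id
        for m in network.metabolites.values()
        if not m.is_media and m.n_atoms > 0
    ]
    s = np.zeros((len(internal), len(reactions)))
    for j, r in enumerate(reactions):
        for i, met in enumerate(internal):
            s[i, j] += sum(1 for m, _l in r.products if m == met)
            s[i, j] -= sum(1 for m, _l in r.substrates if m == met)
    cost = rng.random(len(reactions))
    res = linprog(
        cost, A_eq=s, b_eq=np.zeros(len(internal)), bounds=(0.1, 50.0),
        method="highs",
    )
    if not res.success:
        raise TandemerError(
            "no strictly positive steady-state flux vector exists for this network"
        )
    return {r.id: float(v) for r, v in zip(reactions, res.x)}


def random_tracers(network: Network, seed: int = 0, alpha: float = 0.5) -> TracerSpec:
    """Dirichlet-distributed isotopomer labeling for every media metabolite."""
    rng = np.random.default_rng(seed)
    tracers: TracerSpec = {}
    for met in network.metabolites.values():
        if met.is_media and met.n_atoms > 0:
            values = rng.dirichlet(np.full(1 << met.n_atoms, alpha))
            tracers[met.id] = IsotopomerDistribution(met.id, values).validate()
    return tracers
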