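"""Network model and data-file I/O.

The model format is one reaction per line in the de facto atom-transition
notation used across 13C metabolic flux analysis tools::

    #media A
    v1: A (abcd) -> B (abcd)
    v2: A (abcd) -> C (ab) + D (dc)
    v4: C (ab) <-> D (ab)
    v6: B (abcd) + C (ef) -> E (cdef)
    e_E: E (abcd) ->

Each tracked atom is one character of the label string; a product letter must
appear exactly once on the substrate side; a substrate letter absent from the
products leaves to an untracked sink (e.g. CO2 when unmodeled).  ``<->`` marks
a reversible reaction, which is always expanded into an irreversible pair with
ids suffixed ``_f``/``_b``.  Metabolites listed without a label string carry no
tracked atoms (cofactors) and are ignored by the labeling math.  ``#media``
declares the metabolites whose labeling is supplied by the tracer
specification.  Rotational molecular symmetry is expressed by listing
alternative product mappings separated by ``|`` (equal weights)::

    v7: X (abcd) -> S (abcd) | S (dcba)

Flux vectors, tracer specifications and target MFP lists are RFC-4180 CSV with
headers ``reaction,flux``, ``metabolite,isotopomer,fraction`` and
``metabolite,parent_atoms,product_atoms`` (atom sets as comma-separated
1-based indices).  Results are written as a long-format CSV of feasible
entries plus a JSON companion carrying full matrices and provenance.
"""

from __future__ import annotations

import hashlib
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ModelError, ParseError, ValidationError
from .iso_core import (
    MFP,
    IsotopomerDistribution,
    Metabolite,
    TandemerMatrix,
    feasible_mask,
)

STEADY_STATE_TOL = 1e-6

#: flux vector: reaction id -> non-negative flux (after reversible expansion)
FluxVector = dict[str, float]
#: tracer specification: media metabolite id -> isotopomer distribution
TracerSpec = dict[str, IsotopomerDistribution]


@dataclass(frozen=True)
class Reaction:
    """One irreversible reaction with per-atom substrate→product mapping.

    ``substrates``/``products`` are ``(metabolite id, label string)`` pairs;
    cofactors carry an empty label string.  ``product_alternatives`` holds one
    product list per symmetry-equivalent atom mapping (usually just one); each
    alternative contributes ``1/len(product_alternatives)`` of the flux.
    """

    id: str
    substrates: tuple[tuple[str, str], ...]
    product_alternatives: tuple[tuple[tuple[str, str], ...], ...]

    @property
    def products(self) -> tuple[tuple[str, str], ...]:
        return self.product_alternatives[0]

    @property
    def tracked_substrates(self) -> tuple[tuple[int, str, str], ...]:
        """(substrate index, metabolite, letters) for substrates with atoms."""
        return tuple(
            (k, met, letters)
            for k, (met, letters) in enumerate(self.substrates)
            if letters
        )

    @property
    def n_alternatives(self) -> int:
        return len(self.product_alternatives)

    def atom_map(self, alternative: int = 0) -> dict[int, dict[int, tuple[int, int]]]:
        """Per product instance: product atom (1-based) -> (substrate idx, atom).

        Substrate indices refer to positions in ``self.substrates``.
        """
        source: dict[str, tuple[int, int]] = {}
        for k, (met, letters) in enumerate(self.substrates):
            for pos, letter in enumerate(letters, start=1):
                source[letter] = (k, pos)
        mapping: dict[int, dict[int, tuple[int, int]]] = {}
        for p, (met, letters) in enumerate(self.product_alternatives[alternative]):
            mapping[p] = {
                pos: source[letter] for pos, letter in enumerate(letters, start=1)
            }
        return mapping


@dataclass
class Network:
    """A parsed, validated, fully expanded (irreversible) network."""

    metabolites: dict[str, Metabolite]
    reactions: list[Reaction]
    #: reaction ids created by n-ary splitting: original id -> children ids
    split_children: dict[str, list[str]] = field(default_factory=dict)

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[met_id]
        except KeyError:
            raise ModelError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise ModelError(f"unknown reaction {rxn_id!r}")

    def producers(self, met_id: str) -> list[tuple[Reaction, int]]:
        """All (reaction, product-instance index) pairs producing ``met_id``."""
        out = []
        for r in self.reactions:
            for p, (met, _letters) in enumerate(r.products):
                if met == met_id:
                    out.append((r, p))
        return out

    def consumed_media(self) -> list[str]:
        """Media metabolites appearing on any substrate side."""
        seen = []
        for r in self.reactions:
            for met, _letters in r.substrates:
                if self.metabolites[met].is_media and met not in seen:
                    seen.append(met)
        return seen

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Network)
            and self.metabolites == other.metabolites
            and self.reactions == other.reactions
        )


_TERM_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*(?:\(\s*([A-Za-z0-9]*)\s*\))?\s*$")


def _parse_side(text: str, lineno: int) -> tuple[tuple[str, str], ...]:
    text = text.strip()
    if not text:
        return ()
    terms = []
    for chunk in text.split("+"):
        m = _TERM_RE.match(chunk)
        if not m:
            raise ParseError(f"cannot parse participant {chunk.strip()!r}", lineno)
        terms.append((m.group(1), m.group(2) or ""))
    return tuple(terms)


def _validate_mapping(
    rid: str,
    substrates: tuple[tuple[str, str], ...],
    products: tuple[tuple[str, str], ...],
    lineno: int | None,
) -> None:
    sub_letters: list[str] = []
    for _met, letters in substrates:
        sub_letters.extend(letters)
    if len(set(sub_letters)) != len(sub_letters):
        raise ParseError(f"reaction {rid!r}: duplicate substrate atom letters", lineno)
    prod_letters: list[str] = []
    for _met, letters in products:
        prod_letters.extend(letters)
    if len(set(prod_letters)) != len(prod_letters):
        raise ParseError(f"reaction {rid!r}: duplicate product atom letters", lineno)
    missing = set(prod_letters) - set(sub_letters)
    if missing:
        raise ParseError(
            f"reaction {rid!r}: product letters {sorted(missing)} have no "
            "substrate source",
            lineno,
        )
    n_tracked = sum(1 for _m, letters in substrates if letters)
    if n_tracked > 2:
        raise ParseError(
            f"reaction {rid!r}: {n_tracked} tracked-atom substrates; at most 2 "
            "are supported (use split_nary to rewrite into binary condensations)",
            lineno,
        )


def _split_nary_raw(
    rid: str,
    substrates: tuple[tuple[str, str], ...],
    alternatives: tuple[tuple[tuple[str, str], ...], ...],
    reversible: bool,
    lineno: int | None,
):
    """Rewrite an n-ary condensation into a cascade of binary ones."""
    if reversible:
        raise ParseError(f"reaction {rid!r}: cannot split a reversible n-ary reaction", lineno)
    tracked = [(met, letters) for met, letters in substrates if letters]
    cofactors = [(met, letters) for met, letters in substrates if not letters]
    out = []
    acc_met = tracked[0][0]
    acc_letters = tracked[0][1]
    children = []
    for m, (met, letters) in enumerate(tracked[1:-1], start=1):
        inter = f"_{rid}_cascade{m}"
        child = f"{rid}__s{m}"
        out.append((child, ((acc_met, acc_letters), (met, letters)),
                    (((inter, acc_letters + letters),),), False, lineno))
        children.append(child)
        acc_met, acc_letters = inter, acc_letters + letters
    last_met, last_letters = tracked[-1]
    out.append((rid, ((acc_met, acc_letters), (last_met, last_letters), *cofactors),
                alternatives, False, lineno))
    return out, children


def parse_model(text: str, split_nary: bool = False) -> Network:
    """Parse a model file into a validated :class:`Network`.

    Reversible reactions are expanded into ``_f``/``_b`` irreversible pairs.
    With ``split_nary=True``, reactions with more than two tracked-atom
    substrates are rewritten into a cascade of binary condensations through
    auto-generated intermediate species; otherwise they are rejected.
    """
    media: list[str] = []
    raw: list[tuple] = []  # (id, substrates, alternatives, reversible, lineno)
    seen_ids: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#media"):
                media.extend(line[len("#media"):].split())
            continue  # plain comment
        if ":" not in line:
            raise ParseError("expected 'id: substrates -> products'", lineno)
        rid, _, body = line.partition(":")
        rid = rid.strip()
        if not rid:
            raise ParseError("empty reaction id", lineno)
        if rid in seen_ids:
            raise ParseError(f"duplicate reaction id {rid!r}", lineno)
        seen_ids.add(rid)
        reversible = "<->" in body
        arrow = "<->" if reversible else "->"
        if arrow not in body:
            raise ParseError("missing '->' or '<->'", lineno)
        lhs, _, rhs = body.partition(arrow)
        substrates = _parse_side(lhs, lineno)
        if not substrates:
            raise ParseError(f"reaction {rid!r}: no substrates", lineno)
        alternatives = tuple(
            _parse_side(alt, lineno) for alt in rhs.split("|")
        ) if rhs.strip() else ((),)
        mets_per_alt = [sorted(m for m, _l in alt) for alt in alternatives]
        if any(m != mets_per_alt[0] for m in mets_per_alt[1:]):
            raise ParseError(
                f"reaction {rid!r}: mapping alternatives list different products", lineno
            )
        raw.append((rid, substrates, alternatives, reversible, lineno))

    if split_nary:
        split_children: dict[str, list[str]] = {}
        new_raw = []
        for rid, substrates, alternatives, reversible, lineno in raw:
            n_tracked = sum(1 for _m, letters in substrates if letters)
            if n_tracked > 2:
                pieces, children = _split_nary_raw(
                    rid, substrates, alternatives, reversible, lineno
                )
                new_raw.extend(pieces)
                split_children[rid] = children
            else:
                new_raw.append((rid, substrates, alternatives, reversible, lineno))
        raw = new_raw
    else:
        split_children = {}

    # validate mappings and expand reversible reactions
    reactions: list[Reaction] = []
    for rid, substrates, alternatives, reversible, lineno in raw:
        for alt in alternatives:
            _validate_mapping(rid, substrates, alt, lineno)
        if reversible:
            if len(alternatives) > 1:
                raise ParseError(
                    f"reaction {rid!r}: mapping alternatives on a reversible "
                    "reaction are not supported",
                    lineno,
                )
            back_subs, back_prods = alternatives[0], (substrates,)
            if not back_subs:
                raise ParseError(f"reaction {rid!r}: reversible efflux is meaningless", lineno)
            _validate_mapping(rid + "_b", back_subs, substrates, lineno)
            reactions.append(Reaction(rid + "_f", substrates, alternatives))
            reactions.append(Reaction(rid + "_b", back_subs, back_prods))
        else:
            reactions.append(Reaction(rid, substrates, alternatives))

    # infer atom counts, check consistency
    n_atoms: dict[str, int] = {}
    for r in reactions:
        for met, letters in (*r.substrates, *(t for alt in r.product_alternatives for t in alt)):
            n = len(letters)
            if met in n_atoms and n_atoms[met] != n:
                raise ParseError(
                    f"metabolite {met!r} appears with {n_atoms[met]} and {n} atoms"
                )
            n_atoms.setdefault(met, n)
    for m in media:
        if m not in n_atoms:
            raise ParseError(f"#media declares unknown metabolite {m!r}")
    metabolites = {
        met: Metabolite(met, n, is_media=(met in media))
        for met, n in sorted(n_atoms.items())
    }
    return Network(metabolites, reactions, split_children)


def serialize_model(network: Network) -> str:
    """Canonical text form of a network (all reactions irreversible)."""
    lines = []
    media = [m.id for m in network.metabolites.values() if m.is_media]
    if media:
        lines.append("#media " + " ".join(media))

    def term(met, letters):
        return f"{met} ({letters})" if letters else met

    for r in network.reactions:
        lhs = " + ".join(term(*s) for s in r.substrates)
        rhs = " | ".join(
            " + ".join(term(*p) for p in alt) for alt in r.product_alternatives
        )
        lines.append(f"{r.id}: {lhs} -> {rhs}".rstrip())
    return "\n".join(lines) + "\n"


def model_hash(network: Network) -> str:
    return hashlib.sha256(serialize_model(network).encode()).hexdigest()[:16]


def _read_csv(source) -> pd.DataFrame:
    if isinstance(source, Path):
        return pd.read_csv(source, dtype=str)
    if isinstance(source, str) and "\n" not in source and source.endswith(".csv"):
        return pd.read_csv(source, dtype=str)
    return pd.read_csv(io.StringIO(source), dtype=str)


def parse_fluxes(source, network: Network | None = None) -> FluxVector:
    """Parse a ``reaction,flux`` CSV (path or text) into a flux vector.

    With a network, every reaction must receive a flux; reactions created by
    n-ary splitting inherit the flux of their parent reaction.
    """
    df = _read_csv(source)
    if not {"reaction", "flux"} <= set(df.columns):
        raise ValidationError("flux CSV needs columns 'reaction,flux'")
    fluxes: FluxVector = {}
    for _, row in df.iterrows():
        v = float(row["flux"])
        if v < 0:
            raise ValidationError(
                f"negative flux {v} for {row['reaction']!r}; expand reversible "
                "reactions into non-negative forward/backward pairs"
            )
        if row["reaction"] in fluxes:
            raise ValidationError(f"duplicate flux entry for {row['reaction']!r}")
        fluxes[row["reaction"]] = v
    if network is not None:
        for parent, children in network.split_children.items():
            if parent in fluxes:
                for child in children:
                    fluxes.setdefault(child, fluxes[parent])
        known = {r.id for r in network.reactions}
        unknown = set(fluxes) - known
        if unknown:
            raise ValidationError(f"flux entries for unknown reactions {sorted(unknown)}")
        missing = known - set(fluxes)
        if missing:
            raise ValidationError(f"missing flux for reactions {sorted(missing)}")
    return fluxes


def parse_tracers(source, network: Network) -> TracerSpec:
    """Parse a ``metabolite,isotopomer,fraction`` CSV into a tracer spec."""
    df = _read_csv(source)
    if not {"metabolite", "isotopomer", "fraction"} <= set(df.columns):
        raise ValidationError("tracer CSV needs columns 'metabolite,isotopomer,fraction'")
    tracers: TracerSpec = {}
    for met_id, group in df.groupby("metabolite", sort=False):
        met = network.metabolite(str(met_id))
        if not met.is_media:
            raise ValidationError(f"tracer given for non-media metabolite {met.id!r}")
        patterns = {str(r["isotopomer"]): float(r["fraction"]) for _, r in group.iterrows()}
        dist = IsotopomerDistribution.from_patterns(met.id, met.n_atoms, patterns)
        total = dist.values.sum()
        if abs(total - 1.0) > STEADY_STATE_TOL:
            raise ValidationError(
                f"tracer fractions for {met.id!r} sum to {total!r}, not 1"
            )
        tracers[met.id] = dist.validate()
    missing = [m for m in network.consumed_media() if m not in tracers]
    if missing:
        raise ValidationError(f"no tracer entry for consumed media metabolites {missing}")
    return tracers


def _parse_atoms(cell) -> tuple[int, ...]:
    cell = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell)
    cell = cell.strip()
    if not cell:
        return ()
    return tuple(int(tok) for tok in cell.split(","))


def parse_targets(source, network: Network | None = None) -> list[MFP]:
    """Parse a target-MFP CSV; duplicates are dropped canonically."""
    df = _read_csv(source)
    if not {"metabolite", "parent_atoms", "product_atoms"} <= set(df.columns):
        raise ValidationError(
            "target CSV needs columns 'metabolite,parent_atoms,product_atoms'"
        )
    targets: list[MFP] = []
    for _, row in df.iterrows():
        mfp = MFP(
            str(row["metabolite"]),
            _parse_atoms(row["parent_atoms"]),
            _parse_atoms(row["product_atoms"]),
        )
        if network is not None:
            met = network.metabolite(mfp.metabolite)
            if any(a > met.n_atoms for a in mfp.parent):
                raise ValidationError(
                    f"target {mfp}: atom index beyond {met.n_atoms} atoms"
                )
        if mfp not in targets:
            targets.append(mfp)
    return targets


def total_production_flux(network: Network, met_id: str, fluxes: FluxVector) -> float:
    """Total flux producing ``met_id``, counting product-instance multiplicity."""
    total = 0.0
    for r in network.reactions:
        total += fluxes[r.id] * sum(1 for m, _l in r.products if m == met_id)
    return total


@dataclass
class SteadyStateReport:
    """Per-metabolite production-minus-consumption residuals."""

    residuals: dict[str, float]
    production: dict[str, float]
    ok: bool
    tol: float

    def failing(self) -> list[str]:
        return [
            m
            for m, r in self.residuals.items()
            if abs(r) > self.tol * max(1.0, self.production[m])
        ]


def check_steady_state(
    network: Network, fluxes: FluxVector, tol: float = STEADY_STATE_TOL
) -> SteadyStateReport:
    """Metabolite balance residuals for every non-media tracked metabolite."""
    residuals: dict[str, float] = {}
    production: dict[str, float] = {}
    for met in network.metabolites.values():
        if met.is_media or met.n_atoms == 0:
            continue
        prod = cons = 0.0
        for r in network.reactions:
            v = fluxes.get(r.id, 0.0)
            cons += v * sum(1 for m, _l in r.substrates if m == met.id)
            prod += v * sum(1 for m, _l in r.products if m == met.id)
        residuals[met.id] = prod - cons
        production[met.id] = prod
    report = SteadyStateReport(residuals, production, ok=True, tol=tol)
    report.ok = not report.failing()
    return report


def _mfp_record(mfp: MFP) -> dict:
    return {
        "metabolite": mfp.metabolite,
        "parent_atoms": ",".join(map(str, mfp.parent)),
        "product_atoms": ",".join(map(str, mfp.product)),
    }


def write_results(
    results: dict[MFP, TandemerMatrix],
    csv_path,
    json_path=None,
    metadata: dict | None = None,
) -> None:
    """Write tandemer matrices as long CSV (feasible entries only) + JSON."""
    rows = []
    for mfp in sorted(results):
        t = results[mfp]
        mask = feasible_mask(t.n_parent, t.n_product)
        for i in range(t.n_parent + 1):
            for j in range(t.n_product + 1):
                if mask[i, j]:
                    rows.append({**_mfp_record(mfp), "i": i, "j": j,
                                 "abundance": t.values[i, j]})
    pd.DataFrame(
        rows,
        columns=["metabolite", "parent_atoms", "product_atoms", "i", "j", "abundance"],
    ).to_csv(csv_path, index=False)
    if json_path is not None:
        payload = {
            "metadata": metadata or {},
            "results": [
                {**_mfp_record(mfp), "values": results[mfp].values.tolist()}
                for mfp in sorted(results)
            ],
        }
        Path(json_path).write_text(json.dumps(payload, indent=1))


def read_results_json(json_path) -> tuple[dict[MFP, TandemerMatrix], dict]:
    """Round-trip reader for the JSON written by :func:`write_results`."""
    payload = json.loads(Path(json_path).read_text())
    results: dict[MFP, TandemerMatrix] = {}
    for rec in payload["results"]:
        mfp = MFP(
            rec["metabolite"],
            _parse_atoms(rec["parent_atoms"]),
            _parse_atoms(rec["product_atoms"]),
        )
        results[mfp] = TandemerMatrix(np.array(rec["values"]), mfp)
    return results, payload.get("metadata", {})
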