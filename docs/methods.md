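# Methods

## Problem and model

Tandem mass spectrometry of an isotope tracing experiment measures, for a
metabolite fragment pair (MFP) `A^N_K` — a parent fragment `N ⊆ {1..n}`
retained in the MS1 ion and a product fragment `K ⊆ N` retained in the MS2
ion — the relative abundance of every transition `[M+i] > [m+j]` between
parent and product mass-isotopomers.  These abundances form the tandemer
distribution matrix `[A]^N_K`, a `(|N|+1) × (|K|+1)` probability matrix.  A
transition is feasible iff `i − (|N| − |K|) ≤ j ≤ i`, so exactly
`(|N| − |K| + 1)(|K| + 1)` entries can be nonzero.

At isotopic steady state the matrix of every balanced MFP obeys a flux
balance over its producing reactions,

    [A]^N_K · Σᵢ vᵢ  =  Σ_uni [S(A^N_K, i)] · vᵢ
                        + Σ_bi [S1(A^N_K, i)] ⊗ [S2(A^N_K, i)] · vᵢ ,

where `S(·, i)` are the substrate MFPs obtained by pulling `N` and `K` back
through reaction `i`'s atom map, and `⊗` is the two-dimensional Cauchy
product (label counts of independently labeled condensation partners add, so
their count distributions convolve).

### Assumptions

* Isotopic (and metabolic) steady state; the flux vector must balance every
  non-media tracked metabolite to `1e-6 · max(1, production)`.
* A single tracer element (e.g. ¹³C); no natural-isotope-abundance
  correction; ideal measurements (no noise model).
* Reversible reactions are modeled as explicit forward/backward irreversible
  pairs; all fluxes are non-negative.
* At most two substrates carry tracked atoms per reaction.  Reactions with
  more are rewritten (opt-in) into a cascade of binary condensations through
  synthetic intermediates, which is exact for labeling purposes.
* Media metabolites have externally known labeling.  A media metabolite that
  is also produced internally keeps its fixed tracer labeling: media supply
  is treated as one more producing reaction with a known source, and the
  known source wins by definition of "media".

## Algorithm

1. **Decomposition.**  Starting from the requested target MFPs, substrate
   MFPs are added recursively through every producing reaction until
   closure.  MFPs of media metabolites become boundary nodes.  A
   condensation in which one substrate receives no parent atoms is demoted
   to a uni-substrate link.
2. **Clustering and ordering.**  Uni-substrate pullback preserves `(|N|,
   |K|)` and condensation strictly shrinks the parent on both sides, so the
   dependency graph's strongly connected components (computed with
   `networkx`) form a cascade ordered by non-decreasing parent-fragment
   size.  The topological order is made deterministic by sorting ties on
   `(parent size, smallest canonical MFP name)`; unknowns within a cluster
   are in canonical name order, so repeated runs are byte-identical.
3. **Cluster solves.**  Each cluster yields `A_i X_i = B_i Y_i` with `X_i`
   rows the vectorized unknown matrices (infeasible entries removed, `(i,j)`
   in row-major order), `Y_i` the known rows (boundary matrices, earlier
   clusters, and Cauchy-product rows memoized per distinct source pair), a
   negative total-production diagonal in `A_i`, `+v` for intra-cluster
   uni-links and `−v` in `B_i` — the sign convention of the published
   worked example, whose printed cluster matrix is the transpose of this
   row-per-balance layout (its columns, not rows, balance against `B_i`).
   Systems are solved by LU factorization (dense below 400 unknowns, sparse
   `splu` above), never by explicit inversion.

## Numerical choices

* Solved rows must sum to 1 within `1e-9` *without* renormalization —
  conservation is structural, so a violation raises instead of being hidden.
* Floating-point negatives with magnitude `< 1e-12` are clamped to zero;
  anything more negative raises (it signals an inconsistent model or a
  near-singular system).
* A cluster whose 1-norm condition estimate exceeds `1e12` raises, naming
  its MFPs; a needed metabolite with zero total production flux raises (its
  labeling is undefined at steady state).
* Degenerate inputs: an empty product fragment is legal (the matrix is a
  column holding the parent MID); an empty parent fragment is only allowed
  as the demoted side of a condensation and never becomes a variable.

## Brute-force oracles

Two independent validators solve the complete isotopomer balance equations:

* a damped fixed-point iteration on isotopomer fractions (damping 0.5,
  residual = largest absolute balance violation, tolerance `1e-12`, at most
  10,000 iterations), robust on cyclic networks;
* the cumomer cascade: cumulative labeling probabilities solved weight by
  weight as sparse linear systems and converted back to isotopomer space by
  a Möbius (inverse superset-sum) transform.

Both are restricted to networks with at most `2^16` isotopomers, must agree
below `1e-10`, and marginalize onto any MFP for comparison with the cascade
solver.  The headline correctness property — equality below `1e-8` on
hundreds of random cyclic/condensing networks — is exercised by the test
suite at 100 seeded networks per run (≤ 7 metabolites, ≤ 6 atoms each, ≤ 12
reactions), a size at which the brute-force oracle is exact and fast while
still covering every structural feature the solver handles.

### Cumomer counting conventions

`cumomer_report` counts `Σ 2^n` over *all* tracked metabolites, media
included: the media distributions are inputs, but their isotopomers are part
of the model a full-space method must represent.  Cluster sizes follow the
classic cascade convention — cumomers of the balanced metabolites grouped by
labeling weight, weight-0 excluded — because that is the unit in which the
cumomer method factorizes its linear algebra; strongly-connected-component
sizes are available as an alternative (`compute_scc=True`) and are much
smaller on cyclic networks.  On the methionine model these conventions give
52,306 total cumomers and a largest weight level (weight 7) of
C(15,7) + C(14,7) + C(11,7) = 10,197.

## Fixtures

* **Toy network.**  Media metabolite A (4 carbons) feeding B, C, D, E with
  one cleavage (v2), one fragment transfer (v3), two reversible exchanges
  (v4, v5) and one condensation (v6).  The atom maps are reconstructed from
  the worked example's printed balance equations, which pin them up to
  relabeling; the default flux vector (v1=3, v2=1, v3=1, v4=0.5/0.5,
  v5=2/1, v6=1 plus effluxes 1/1/2) balances the network exactly, and the
  default tracer is 50 % 1,2-¹³C₂ / 50 % unlabeled A.
* **Methionine metabolism.**  A lumped model of the mammalian
  transmethylation cycle, polyamine branch and methionine salvage:
  methionine (5 C), SAM (15 C), SAH (14 C), MTA (11 C) and homocysteine
  (4 C) balanced; medium methionine (5 C), ATP (10 C, the adenosyl donor)
  and the 5-methyl-THF methyl group (1 C) as media.  The salvage atom map
  follows the known chemistry (ribose C-1′ lost as formate, C-2′…C-5′ to
  methionine C-1…C-4, S-methyl retained); the polyamine step is lumped so
  the decarboxylated carbon and the aminopropyl group leave the tracked
  scope.  Fluxes are a plausible positive steady state (70 % of SAM to
  transmethylation, 30 % to polyamines, salvage closed); the default tracer
  is 50 % U-¹³C₅ medium methionine.  The default target set uses intact
  metabolites as parents with the adenine group (SAM/SAH/MTA) or the four
  non-methyl carbons (Met/HCys) as products.
* **Random networks.**  The generator emulates small central-metabolism-like
  topologies: atom-conserving uni transfers and binary condensations with
  sink atoms, a guaranteed producer chain from the medium, optional
  reversible exchange (cycles), and per-metabolite effluxes; fluxes are a
  strictly positive point of the flux polytope found by linear programming,
  and tracers are Dirichlet-distributed.  It does **not** emulate large
  carbon counts, multiple compartments, symmetric molecules beyond the
  explicit alternative-mapping syntax, or realistic flux magnitudes — so
  passing property tests demonstrate algorithmic correctness, not biological
  realism of any particular model.

## Known limitations

* The response to tracer labeling is bilinear, not linear, whenever two
  condensation substrates descend from the same medium species; mixture
  experiments therefore cannot generally be predicted by mixing pure-tracer
  simulations.
* No flux fitting, gradients, or non-stationary (time-course) simulation;
  this package only simulates steady-state distributions for a given flux
  vector.
* No natural-abundance correction and a single label element.
* The brute-force oracles are deliberately capped at `2^16` isotopomers.
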