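# Methods

## Site-graph formalism

A molecule instance carries a type name and an ordered list of named
components; a component holds an optional internal state and a bond slot
(unbound, an integer bond label, `!+` "bound to something", or `!?`
"bound or not").  A *pattern* may omit components and states; a *species*
is a connected, fully specified, wildcard-free graph.  Matching
enumerates every injective embedding that preserves types, names,
specified states and bond structure — automorphic duplicates included,
so a trivalent pattern `L(r,r,r)` has six self-embeddings.  Per-embedding
counting is deliberate: propensities and reaction multiplicities divide
by the rule's symmetry factor (below), which makes the convention exact
and keeps observables consistent with embedding counts.

Canonical labels are computed by iterative neighbourhood refinement with
individualization on ties (minimum label over branches), then serialized
as a BNGL-style string with bond labels renumbered along the canonical
order; residual within-molecule ties among identical components bonded to
the same partner are resolved by brute-force minimization over the (tiny)
tie classes.  Equal labels hold iff the graphs are isomorphic; the test
suite checks this against a networkx VF2 oracle on random complexes.
Worst-case cost is exponential for highly symmetric aggregates (rings of
identical molecules); such labels are only computed in the
species-ranking utility, never in the simulation inner loop.

## Rules and the symmetry factor

A rule stores ordered reactant patterns, a product description, a rate
constant, and a derived transformation list (bond add/delete, state
change, molecule add/delete).  Transformations come from a molecule
alignment between the two sides — by type and order of appearance for
parsed rules (the BNGL convention), or an explicit alignment for rules
built by the PNE machinery.

The symmetry factor `s_r` is the number of reactant-side automorphisms
(including permutations of identical reactant patterns) that leave the
transformation's action sites fixed as a set.  It converts raw
embedding-tuple counts into event counts.  Examples: `A(b)+B(a)` gives
1; `A(a)+A(a) -> A(a!1).A(a!1)` gives 2; `L(r,r,r)+R(l)` binding the
first `r` gives 2 (the two untouched sites permute); a population-mapping
rule that deletes a whole complex has `s_r` equal to the full
automorphism count of the species, which is exactly what makes its
propensity `k_lump * n` under per-embedding counting.  The convention is
validated against exact chemical-master-equation enumeration on a tiny
dimerization system, since no closed definition was available to follow.

Bimolecular rules are intermolecular only: if both selected reactants lie
in one complex the event is null (time advances, nothing fires).  This
matches network-free simulator semantics and is what the aggregation
models assume; no intramolecular binding variant is provided.

Molecule deletion removes the molecule and its bonds; remaining fragments
become separate complexes.  No whole-complex delete flag exists — the
packaged models avoid the ambiguity.

## Network generation and SSA

Network generation applies all rules to the seed species, canonicalizes
and deduplicates products, and iterates until a fixed point; a species or
iteration limit (defaults 50 000 / 100) raises a named truncation error,
since rule-based models can encode infinite networks.  Each reaction is
recorded once per (rule, reactant multiset, product multiset) with an
integer multiplicity equal to its embedding-tuple count.  Propensities
use the ordered-pair convention — `rate*mult/sym * n_i*n_j`, or
`* n*(n-1)` for an identical pair, `* n` unimolecular — which is exact
for symmetric rules without requiring the tuple count to be divisible by
the symmetry factor.  The SSA is a plain direct method (no dependency
graph or propensity sorting; performance engineering is out of scope).
Null reactions (identical reactant and product multisets) are kept so
firing counts remain comparable across engines.

## Partial network expansion

The three steps are described in the README.  Conventions:

* **Duplicate merging.**  The cartesian product over per-embedding
  matches produces duplicate derived rules (e.g. the six embeddings of
  `L(r,r,r)` into free ligand); duplicates (same slot assignment,
  isomorphic products) are merged and the multiplicity is absorbed into
  the derived rate constant.  Derived rules inherit the *source* rule's
  symmetry factor — recomputing it after substitution would be wrong,
  e.g. barbed- vs pointed-end monomer addition both derive
  `pop_A()+pop_A()` rules whose reactants look identical but whose
  events are ordered pairs.  The published rule totals (42, 9, 25,
  25/38, 159) all reproduce under this convention, which settles the
  open question of whether to merge.
* **Product substitution.**  A product component is swapped for its
  counter only when it is unambiguously that species — fully specified
  and isomorphic to a mapped species.  Ambiguous products (patterns that
  only *might* be a population species once instantiated) stay
  structured; the appended mapping rules detect the instances at run
  time and lump them at `k_lump`.
* **Fast vs. safe mode.**  Fast mode discards a self-match when the
  pattern equals a population species; it is exact only as
  `k_lump -> infinity`, but in practice `k_lump = 10^4/s` (`10^5/s` for
  the EGFR model) is orders of magnitude above every model timescale and
  the firing-count tests cannot distinguish the engines.  Safe mode
  keeps all self-matches and is exact for any `k_lump`.  Infinite
  `k_lump` is not supported.
* **Seeds and observables.**  Seed species isomorphic to a mapped
  species initialize the counter directly (otherwise startup would need
  O(N) mapping firings).  Observables gain counter terms weighted by
  their embedding count into each structured population species, which
  is required for trajectory equivalence and follows the same
  per-embedding convention as everything else.

Re-expanding the hybrid model with the same maps derives nothing new
(expansion is idempotent); this is the coverage property asserted in the
tests.

## The population-adapted network-free engine

State: explicit particles (mutable pointer-bonded molecules grouped into
complexes) plus a counter per unstructured population species.  Per-slot
match totals are maintained incrementally: patterns are compiled for
rooted matching (breadth-first order, bond-anchored candidates), and
after each firing only molecules within the maximum pattern eccentricity
of the touched region are recounted.  A full from-scratch recomputation
(`propensities_brute`) is kept as a debug cross-check and is asserted
against the incremental totals in the tests.  Compiled patterns are
shared between rules only when their written form (molecule and component
order) is identical, never merely up to isomorphism — transformation loci
address pattern positions by index.

Randomness is consumed in a fixed order per event: (1) exponential
waiting time at the total propensity, (2) rule choice by linear scan,
(3) per-slot reactant selection — a population species deterministically,
a particle root by bounded rejection sampling and then a uniform choice
among that root's embeddings, (4) the symmetric-population rejection
draw.  Identical (model, seed) pairs give bit-identical trajectories.

Null events (same-complex bimolecular selection; same-counter selection
rejected with probability `1/p`) advance time but are not counted as
firings.  Mapping-rule firings are counted separately and excluded from
cross-engine firing comparisons.  Counters are asserted non-negative;
zero-component population molecules never appear as particles and
structured patterns never match counters, so a pattern matches particles
or populations exclusively.  A configurable particle cap aborts runaway
aggregate growth with a diagnostic.

## Example-model reconstructions

The packaged models are re-encoded from the published model structures;
where a parameter was not printed it was chosen once at the published
order of magnitude, and none of the asserted counts depend on rate
values.

* **Receptor activation** (16 rules = 6 unidirectional + 5 reversible):
  ligand L binds receptor R; two ligand-dependent tyrosines; phospho-y1
  recruits adaptor A which is activated at the receptor and recruits B;
  phospho-y2 recruits B directly; B recruits C.  This structure
  reproduces every printed statistic simultaneously: 56 species (48
  receptor-containing, 8 receptor-free), 287 reactions, the 1-and-2
  match counts of rule 11f with its 6 derived rules, and the 42-rule
  hybrid.  Rates are chosen so the eight receptor-free species are also
  the high-population species (ligand capture strong, activated adaptor
  long-lived) — the premise of the lumping method — which is what makes
  the threshold-selection test able to recover the hand-picked set from
  a pre-simulation.
* **TLBR**: standard 4-rule trivalent-ligand bivalent-receptor encoding
  (capture, two crosslinking context rules, unbinding); ligand and
  receptor totals 4.2e6 and 1.1e6 per cell, crosslinking strength set in
  the solution-gel coexistence regime (aggregates of ~100 molecules at
  f = 0.001 while many small clusters persist).
* **Actin** (21 rules): linear filaments via barbed/pointed sites,
  ATP/ADP-Pi/ADP subunit states, both-end addition and state-dependent
  loss, random hydrolysis and phosphate release, nucleotide exchange on
  free monomer, ADF/cofilin binding to ADP subunits and severing on the
  pointed side of a decorated subunit.  Free ATP-monomer and free ADF
  are the two population species; PNE yields 25 rules.
* **FcεRI gamma2** (24 unidirectional rules): the published receptor
  model with a bivalent ligand, constitutive and SH2-anchored Lyn, Syk
  transactivation — with *two identical* gamma components per receptor.
  The species arithmetic (84 receptor configurations; 6 + 84 + 84 +
  84·85/2 = 3744 species) and the generated 58 276 reactions match the
  published counts exactly, confirming the reconstruction.  Population
  sets: free ligand only, or additionally cytosolic Lyn and the four Syk
  phosphoforms (25 and 38 rules after PNE).
* **EGFR extended** (113 unidirectional rules): a composite of a
  rule-based receptor core (ligand binding, dimerization,
  transphosphorylation, explicit receptor phosphatase, Grb2/Shc/Sos
  recruitment, internalization/recycling), an allosterically regulated
  Sos/GAP Ras module, and an enzyme-explicit Raf/MEK/ERK cascade with
  nuclear translocation, an Elk readout, and ERK feedback onto Sos and
  Raf.  The 29 population species (ligand, Ras- and cascade-layer
  species, cytosolic phosphatases) give 159 rules after PNE.  The full
  network expansion of this model is far beyond desk scale and its size
  is *not* asserted anywhere in the test suite.

The random-model generator used by the property tests emits finite
models by construction (a tree-structured binding topology over a typed
hierarchy, plus state-flip rules) with a random lumpable subset; defaults
are bounded (≤4 types, ≤10 rule lines, seed counts 20–80).

## Statistical protocol and its reduction

The accuracy protocol follows the published one: total reaction firings
per run compared across SSA, network-free and hybrid engines with the
two-sided Mann-Whitney U test (exact for small tie-free samples, normal
approximation with tie correction otherwise), and equilibrium
distributions (TLBR cluster counts, actin polymer lengths) compared with
a two-sample chi-squared test on a common 20-bin histogram with
low-expectation bins merged.  Full-scale runs (40 replicates, 10^5 s,
10^4 samples, f up to 1) are replaced by desk-scale ones — f = 0.001 for
TLBR/actin/FcεRI, f = 0.02 for receptor activation, horizons chosen so a
run fires 10^2–10^3 events, 20 runs per engine, 5% significance.  The
procedures are identical; only the scale differs.  A green equivalence
test therefore establishes statistical indistinguishability at these
scales, not a reproduction of the published full-scale performance
figures (memory/run-time panels are out of scope entirely).

## Numerical and degenerate-case choices

* Waiting times use `rng.exponential(1/total)`; zero total propensity
  ends the run with a flat trajectory.
* Seed counts and volume-scaled counts round to nearest integer;
  volume fraction f scales bimolecular rate constants by 1/f and leaves
  unimolecular rates (including `k_lump`) untouched.
* The chi-squared comparison raises on degenerate binning (all samples
  equal, or too few to fill two bins) rather than reporting a
  meaningless p-value.
* Threshold-based selection ranks canonical labels by time-averaged
  population over one network-free pre-simulation; candidates that fail
  species validation are skipped with a warning.  Lower thresholds give
  supersets of higher ones.

## Known limitations

* Compartments, functional rate laws, energy patterns, and molecule
  hierarchies are out of scope; the dialect covers the packaged models.
* Fast-mode PNE is approximate for finite `k_lump` (bias of order
  model-rate/`k_lump`); use safe mode when in doubt.
* Canonical labeling can be exponential on highly symmetric aggregates.
* The SSA recomputes all propensities per event (no dependency graph),
  and the network-free engine uses a linear rule scan; both are
  correctness-first implementations.
* Automated/dynamic lumping during a run (re-expanding when a species
  becomes abundant) is not implemented; population species are fixed
  before PNE.
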