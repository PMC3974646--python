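# hppsim — hybrid particle/population simulation of rule-based models

Rule-based models (BNGL, Kappa) describe biochemistry as graph-rewriting
rules over structured molecules, sidestepping the combinatorial explosion
of species that plagues explicitly enumerated reaction networks.  They can
be simulated two ways: expand the rules into a full network and run
Gillespie's SSA (memory grows with the network), or run a *network-free*
particle simulator that matches rule patterns against explicit molecular
complexes at run time (memory grows with the number of particles).
Neither is ideal when a system has both a huge network **and** huge
numbers of particles — the common case for receptor signaling, where a
handful of simple, abundant species (free ligand, free adaptors) dominate
the particle count.

`hppsim` implements the **hybrid particle/population (HPP)** method for
that regime.  The user names a set of *population species* to lump into
unstructured counters via population-mapping rules
(`Egf(r) -> pop_Egf()` at a lumping rate constant `k_lump`).  The model
is then transformed by **partial network expansion (PNE)**:

1. match every reactant pattern of every rule into the structured
   population species, keeping a self-match unless the pattern *equals*
   one of them (a "safe" mode always keeps self-matches and is exact for
   any `k_lump`);
2. apply the rule to the cartesian product of the collected matches,
   producing derived rules;
3. replace structured population species by their unstructured
   counterparts on both sides (ambiguous products stay structured — the
   appended mapping rules lump them at run time).

The hybrid model is run by a population-adapted network-free simulator in
which the propensity of rule *r* is

    a_r = (k_r / s_r) * prod_j  sum_k  p_k * M_jk

with `k_r` the rate constant, `s_r` the symmetry factor, `p_k` the
population of complex *k* (1 for particles) and `M_jk` the number of
embeddings of reactant pattern *j* into complex *k* (0 or 1 for a
counter).  With no populations this is exactly the network-free
propensity; with everything lumped it is exactly the SSA propensity.
Symmetric population reactions (`pop_A() + pop_A() -> ...`) reject the
event with probability `1/p` so a molecule never reacts with itself.

The package provides, as plain Python plus a `hppsim` command-line tool:

* a BNGL-subset reader/writer with population extensions (`hppsim.bngl`),
* site-graph pattern matching, canonical labeling and rule application
  (`hppsim.sitegraph`, `hppsim.model`),
* reaction-network generation and an exact direct-method SSA
  (`hppsim.network`),
* PNE (`hppsim.pne`) and the population-adapted network-free engine
  (`hppsim.engine`),
* packaged example models (receptor activation, trivalent-ligand
  bivalent-receptor, actin polymerization, FcεRI *gamma2*, an extended
  EGFR cascade), a random-model generator, cross-engine statistical
  equivalence tests, and threshold-based population-species selection
  (`hppsim.fixtures`, `hppsim.validate`).

## Worked example

```python
from hppsim import (build_fixture, FixtureSpec, generate_network,
                    transform_model, simulate)

model = build_fixture(FixtureSpec("receptor_activation"))
net = generate_network(model)
print(f"network: {net.n_species} species, {net.n_reactions} reactions")

hyb = transform_model(model)            # PNE with the 8 population species
c = hyb.rule_counts()
print(f"hybrid rules: {c['particle']} particle, {c['mixed']} mixed, "
      f"{c['population']} population, {c['mapping']} mapping "
      f"({c['total']} total)")

small = build_fixture(FixtureSpec("receptor_activation", f=0.02))
traj = simulate(transform_model(small), 30.0, seed=1, n_steps=30)
print(f"HPP firings: {traj.firings_excluding_mapping} "
      f"(+{traj.mapping_firings} mapping, {traj.null_events} null events)")
```

prints

```
network: 56 species, 287 reactions
hybrid rules: 14 particle, 11 mixed, 9 population, 8 mapping (42 total)
HPP firings: 451 (+23 mapping, 0 null events)
```

The 16-rule receptor activation model encodes a 56-species, 287-reaction
network (48 species contain the receptor).  Lumping the eight
receptor-free species turns it into a 42-rule hybrid model.  The last
lines run the hybrid engine at 2% of cell volume: 451 ordinary rule
firings occurred, plus 23 firings of the mapping rules that vacuumed
transient structured population species into their counters (those are
excluded from firing counts when comparing engines, since SSA and the
network-free engine have no analogue).

The same pipeline from the shell:

```sh
hppsim generate-network src/hppsim/data/receptor_activation.bngl
hppsim pne src/hppsim/data/tlbr.bngl -o tlbr_hpp.bngl
hppsim simulate src/hppsim/data/tlbr.bngl --method hpp -f 0.001 \
       --t-end 100 --seed 1 -o tlbr.gdat
hppsim validate src/hppsim/data/receptor_activation.bngl -f 0.02 \
       --t-end 30 --with-ssa
```

## Acceptance script

`scripts/acceptance.py` exercises the package's main computation end to
end — it loads the receptor-activation model, generates the reaction
network, performs partial network expansion, and runs one trajectory with
each engine (SSA, network-free, hybrid) from the given seed:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model formalism, the PNE algorithm and
its conventions (symmetry factors, duplicate merging, fast vs. safe
mode), the engine's event loop and randomness order, the example-model
reconstructions, and known limitations.
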