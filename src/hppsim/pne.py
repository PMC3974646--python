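"""Partial network expansion: rule-based model -> hybrid particle/population.

The transformation enumerates every way the reactant patterns of each rule
can act on the chosen population species, in three steps per rule:

1. match every reactant pattern into the set of structured population
   species, and collect a self-match unless the pattern *equals* (is
   isomorphic to, as a fully specified species) one of them — the "fast"
   mode; "safe" mode always retains the self-match and is exact for any
   lumping rate constant;
2. apply the rule to every combination (cartesian product) of the collected
   matches, yielding a set of derived rules;
3. replace structured population species on either side of each derived
   rule with their unstructured counterparts (product occurrences that are
   only *potentially* population species stay structured — the appended
   population-mapping rules gather those up at rate ``k_lump``).

Derived rules that coincide after canonicalization are merged, with the
embedding multiplicity absorbed into the derived rate constant; the source
rule's symmetry factor is inherited so fluxes are preserved exactly.
"""

from __future__ import annotations

import itertools

from .sitegraph import (SiteGraph, Molecule, identity_match, find_matches,
                        canonical_form, canonical_label, isomorphic)
from .model import (ModelDocument, ModelError, Rule, PopulationMap,
                    Observable, MoleculeType, species_equals_pattern)


class PNEError(ModelError):
    pass


class DerivedRuleSet:
    """Expansion record for one source rule.

    ``entries`` holds the deduplicated cartesian-product assignments:
    (assignment, matches, product graphs, product origins, multiplicity),
    where assignment[j] is ``None`` for the self-match of slot j or the
    population-map index bound to that slot.  ``derived`` holds the final
    rules after population substitution (tagged particle/mixed/population).
    """

    def __init__(self, source: Rule):
        self.source = source
        self.entries: list = []
        self.derived: list = []

    def counts_by_tag(self):
        out = {"particle": 0, "mixed": 0, "population": 0}
        for r in self.derived:
            out[r.tag] += 1
        return out


def collect_reactant_matchsets(model: ModelDocument, rule: Rule,
                               pop_maps, mode: str = "fast"):
    """PNE step 1: per-reactant alternatives.

    Each slot yields a list of ``("pop", map_index, match)`` entries (one
    per embedding into a structured population species) plus, usually, the
    ``("self", None, identity)`` entry.  In fast mode the self-match is
    dropped when the pattern equals one of the population species.
    """
    if mode not in ("fast", "safe"):
        raise PNEError(f"unknown PNE mode {mode!r}")
    matchsets = []
    for pattern in rule.reactants:
        alts = []
        equals_some = False
        for pmi, pm in enumerate(pop_maps):
            for m in find_matches(pattern, pm.structured):
                alts.append(("pop", pmi, m))
            if species_equals_pattern(model, pattern, pm.structured):
                equals_some = True
        if mode == "safe" or not equals_some:
            alts.append(("self", None, identity_match(pattern)))
        matchsets.append(alts)
    return matchsets


def expand_rule(rule: Rule, matchsets) -> DerivedRuleSet:
    """PNE step 2: apply the rule to every combination of collected matches.

    Combinations that produce identical derived rules (same slot
    assignment, isomorphic products) are merged with their multiplicity
    recorded."""
    drs = DerivedRuleSet(rule)
    acc: dict = {}
    pop_map_cache = {}
    for combo in itertools.product(*matchsets):
        assignment = tuple(pmi for (kind, pmi, _) in combo)
        complexes = []
        matches = []
        for slot, (kind, pmi, m) in enumerate(combo):
            if kind == "self":
                complexes.append(rule.reactants[slot])
            else:
                complexes.append(m.target)
            matches.append(m)
        try:
            products, origins = rule.apply(complexes, matches,
                                           with_origins=True)
        except ModelError as e:
            raise PNEError(
                f"rule {rule.name}: expansion failed for assignment "
                f"{assignment}: {e}") from e
        key = (assignment,
               tuple(sorted(canonical_form(p) for p in products)))
        if key in acc:
            acc[key][-1] += 1
        else:
            acc[key] = [assignment, matches, products, origins, 1]
    _ = pop_map_cache
    for key in acc:
        drs.entries.append(tuple(acc[key]))
    return drs


def substitute_populations(model: ModelDocument, drs: DerivedRuleSet,
                           pop_maps) -> DerivedRuleSet:
    """PNE step 3: swap structured population species for their counters.

    Reactant slots bound to a population species become unstructured
    population reactants.  Product components are swapped only when they
    are unambiguously that species (fully specified and isomorphic);
    ambiguous products stay structured for the mapping rules to collect."""
    rule = drs.source
    structured_labels = [canonical_label(pm.structured) for pm in pop_maps]
    if len(set(structured_labels)) != len(structured_labels):
        raise PNEError("two population maps have isomorphic structured species")

    def pop_graph(pmi):
        return SiteGraph([Molecule(pop_maps[pmi].unstructured_name, [],
                                   is_population=True)])

    drs.derived = []
    seq = 0
    for (assignment, matches, products, origins, mult) in drs.entries:
        reactants = []
        for slot, pmi in enumerate(assignment):
            if pmi is None:
                reactants.append(rule.reactants[slot].copy())
            else:
                reactants.append(pop_graph(pmi))
        out_products = []
        out_origins = []
        for pg, org in zip(products, origins):
            swapped = None
            if model.is_fully_specified_species(pg):
                try:
                    lab = canonical_label(pg)
                except Exception:
                    lab = None
                if lab in structured_labels:
                    swapped = pop_graph(structured_labels.index(lab))
            if swapped is not None:
                out_products.append(swapped)
                out_origins.append([("n", -1)])
            else:
                out_products.append(pg.copy())
                out_origins.append(list(org))
        alignment = {}
        for pi, org in enumerate(out_origins):
            for mi, o in enumerate(org):
                if o[0] == "r" and assignment[o[1]] is None:
                    alignment[(pi, mi)] = (o[1], o[2])
                else:
                    alignment[(pi, mi)] = None
        if all(a is None for a in assignment) and mult == 1:
            name = rule.name
        else:
            seq += 1
            name = f"{rule.name}_h{seq}"
        derived = Rule(name, reactants, out_products,
                       rule.rate * mult, rate_name=rule.rate_name,
                       alignment=alignment, symmetry=rule.symmetry)
        derived.multiplicity = mult
        derived.tag = derived.classify()
        drs.derived.append(derived)
    return drs


def expand_model_rule(model: ModelDocument, rule: Rule, pop_maps,
                      mode: str = "fast") -> DerivedRuleSet:
    """All three PNE steps for one rule."""
    ms = collect_reactant_matchsets(model, rule, pop_maps, mode)
    drs = expand_rule(rule, ms)
    return substitute_populations(model, drs, pop_maps)


class HybridModel(ModelDocument):
    """PNE output: a simulatable model of derived + mapping rules.

    Extra attributes: ``source`` (the input model), ``pop_maps``, and
    ``derived_sets`` (per-source-rule expansion records)."""

    def __init__(self):
        super().__init__()
        self.source = None
        self.pop_maps = []
        self.derived_sets = []

    def rule_counts(self):
        out = {"particle": 0, "mixed": 0, "population": 0, "mapping": 0}
        for r in self.rules:
            if r.is_population_map:
                out["mapping"] += 1
            else:
                out[r.tag or "particle"] += 1
        out["total"] = len(self.rules)
        return out


def transform_model(model: ModelDocument, pop_maps=None, mode: str = "fast",
                    k_lump: float = None) -> HybridModel:
    """Full PNE transform: expand every rule, append one population-mapping
    rule per population species, and rewrite seeds and observables.

    Seed species that are population species initialize the counters
    directly (no startup burst of mapping-rule firings); observables gain
    counter terms weighted by their match count into each structured
    population species."""
    if pop_maps is None:
        pop_maps = model.population_maps
    if k_lump is not None:
        if k_lump <= 0:
            raise PNEError("k_lump must be positive")
        pop_maps = [PopulationMap(pm.structured, pm.unstructured_name, k_lump)
                    for pm in pop_maps]

    hyb = HybridModel()
    hyb.source = model
    hyb.pop_maps = list(pop_maps)
    hyb.parameters = dict(model.parameters)
    hyb.config = dict(model.config)
    hyb.molecule_types = dict(model.molecule_types)
    for pm in pop_maps:
        if pm.unstructured_name not in hyb.molecule_types:
            hyb.molecule_types[pm.unstructured_name] = MoleculeType(
                pm.unstructured_name, [], is_population=True)
        model.check_species(pm.structured, "population map")

    for rule in model.rules:
        if rule.is_population_map:
            continue
        drs = expand_model_rule(model, rule, pop_maps, mode)
        hyb.derived_sets.append(drs)
        hyb.rules.extend(drs.derived)

    for pm in pop_maps:
        mt = hyb.molecule_types[pm.unstructured_name]
        if not mt.is_population:
            raise PNEError(
                f"{pm.unstructured_name} is not a population molecule type")
        target = SiteGraph([Molecule(pm.unstructured_name, [],
                                     is_population=True)])
        mr = Rule(f"_map_{pm.unstructured_name}", [pm.structured.copy()],
                  [target], pm.k_lump, is_population_map=True)
        mr.tag = "particle"
        hyb.rules.append(mr)

    # seeds: population species initialize counters, everything else stays
    structured_labels = {canonical_label(pm.structured): pm.unstructured_name
                         for pm in pop_maps}
    pop_counts: dict = {}
    for g, n in model.seeds:
        lab = canonical_label(g)
        if lab in structured_labels:
            nm = structured_labels[lab]
            pop_counts[nm] = pop_counts.get(nm, 0) + n
        else:
            hyb.seeds.append((g.copy(), n))
    for nm, n in model.pop_seeds:
        pop_counts[nm] = pop_counts.get(nm, 0) + n
    hyb.pop_seeds = sorted(pop_counts.items())

    # observables: add population-counter terms
    for obs in model.observables:
        terms = []
        for pm in pop_maps:
            w = 0.0
            for pat in obs.patterns:
                nm_ = len(find_matches(pat, pm.structured))
                if obs.kind == "Molecules":
                    w += nm_
                elif nm_:
                    w = 1.0
                    break
            if w:
                terms.append((pm.unstructured_name, w))
        hyb.observables.append(Observable(obs.kind, obs.name,
                                          [p.copy() for p in obs.patterns],
                                          terms))
    hyb.population_maps = list(pop_maps)
    return hyb


def assert_expansion_idempotent(model: ModelDocument, hyb: HybridModel,
                                mode: str = "fast") -> bool:
    """Coverage check: expanding the hybrid rule set again (same population
    maps) derives nothing new — every action on the population species was
    already enumerated."""
    def rule_key(r):
        return (tuple(canonical_form(p) for p in r.reactants),
                tuple(sorted(canonical_form(p) for p in r.products)))

    existing = {rule_key(r) for r in hyb.rules if not r.is_population_map}
    for rule in hyb.rules:
        if rule.is_population_map:
            continue
        drs = expand_model_rule(hyb, rule, hyb.pop_maps, mode)
        for d in drs.derived:
            if rule_key(d) not in existing:
                return False
    return True
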