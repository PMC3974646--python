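"""Model objects: molecule types, rules, transformations, population maps.

A :class:`Rule` stores ordered reactant patterns, a product description, an
elementary rate constant and a *transformation list* derived from the mapped
difference between the two sides.  The transformation list — not the product
patterns — is what gets executed when a rule fires, so the same machinery
serves network generation, partial network expansion and the network-free
engine.

Rate-constant conventions: unimolecular rules carry a per-time constant;
bimolecular rules a per-time-per-pair constant (volume scaling is the
caller's business, see the volume-fraction transform in ``fixtures``).
"""

from __future__ import annotations

import itertools
from typing import Optional

from .sitegraph import (
    SiteGraph, Molecule, Component, Match, SiteGraphError,
    find_matches, isomorphic, canonical_label, WILD_BOUND, WILD_ANY,
)


class ModelError(ValueError):
    """Validation failure: undeclared names, malformed rules, bad bonds."""


# ---------------------------------------------------------------------------
# Molecule types
# ---------------------------------------------------------------------------

class MoleculeType:
    """Declared molecule type: component names (with multiplicity) and the
    allowed internal states of each component.  ``is_population`` marks the
    zero-component unstructured counter species used by hybrid models."""

    __slots__ = ("name", "components", "is_population")

    def __init__(self, name, components, is_population=False):
        self.name = name
        self.components = list(components)  # list of (comp_name, states tuple or None)
        self.is_population = is_population
        if is_population and self.components:
            raise ModelError(
                f"population molecule type {name} must have zero components")

    def states_for(self, comp_name):
        for n, states in self.components:
            if n == comp_name:
                return states
        return None

    def to_string(self):
        parts = []
        for n, states in self.components:
            s = n
            if states:
                s += "".join("~" + st for st in states)
            parts.append(s)
        out = f"{self.name}({','.join(parts)})"
        if self.is_population:
            out += " population"
        return out


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------
# Loci refer into the reactant side as (slot, molecule-in-slot, component) or
# into the added-molecule list as ("new", molecule, component).

class Transformation:
    __slots__ = ("kind", "args")

    def __init__(self, kind, *args):
        self.kind = kind
        self.args = args

    def __repr__(self):
        return f"T({self.kind},{self.args})"


class Rule:
    """A unidirectional reaction rule.

    Parameters
    ----------
    reactants : list of SiteGraph
        Ordered reactant patterns; a pattern whose single molecule has
        ``is_population`` set denotes an unstructured population reactant.
    products : list of SiteGraph
        Product complexes as written.
    rate : float
        Elementary rate constant.
    alignment : dict, optional
        Mapping product locus ``(prod_idx, mol_idx)`` -> reactant locus
        ``(slot, mol_idx)`` or ``None`` for synthesized molecules.  When
        omitted, molecules are corresponded by type name in order of
        appearance (the BNGL convention).
    """

    def __init__(self, name, reactants, products, rate,
                 rate_name=None, alignment=None, is_population_map=False,
                 symmetry=None):
        self.name = name
        self.reactants = list(reactants)
        self.products = list(products)
        self.rate = float(rate)
        self.rate_name = rate_name
        self.is_population_map = is_population_map
        self.tag = None          # particle | mixed | population (set by PNE)
        self.multiplicity = 1    # merged duplicate count (PNE bookkeeping)
        if alignment is None:
            alignment = self._default_alignment()
        self.alignment = alignment
        (self.ops, self.new_molecules) = self._derive_ops()
        self._symmetry = symmetry

    # -- molecule correspondence --------------------------------------------

    def _reactant_mols(self):
        out = []
        for slot, pat in enumerate(self.reactants):
            for mi, mol in enumerate(pat.molecules):
                out.append(((slot, mi), mol))
        return out

    def _product_mols(self):
        out = []
        for pi, pat in enumerate(self.products):
            for mi, mol in enumerate(pat.molecules):
                out.append(((pi, mi), mol))
        return out

    def _default_alignment(self):
        rmols = self._reactant_mols()
        pmols = self._product_mols()
        by_type: dict = {}
        for loc, mol in rmols:
            by_type.setdefault(mol.name, []).append(loc)
        align = {}
        used: dict = {}
        for loc, mol in pmols:
            cands = by_type.get(mol.name, [])
            k = used.get(mol.name, 0)
            if k < len(cands):
                align[loc] = cands[k]
                used[mol.name] = k + 1
            else:
                align[loc] = None  # synthesized
        return align

    # -- derive the transformation list -------------------------------------

    def _derive_ops(self):
        rmols = dict(self._reactant_mols())
        pmols = dict(self._product_mols())
        inv = {v: k for k, v in self.alignment.items() if v is not None}

        ops = []
        new_molecules = []  # list of (product locus, Molecule copy)
        new_index = {}

        for ploc, rloc in self.alignment.items():
            if rloc is None:
                new_index[ploc] = len(new_molecules)
                new_molecules.append((ploc, pmols[ploc].copy()))

        # deleted molecules
        for rloc, mol in rmols.items():
            if rloc not in inv:
                ops.append(Transformation("delmol", rloc))

        # component correspondence for aligned molecules; compare states
        comp_corr = {}  # (ploc, pci) -> (rloc, rci)
        for ploc, rloc in self.alignment.items():
            if rloc is None:
                continue
            rmol, pmol = rmols[rloc], pmols[ploc]
            r_by_name: dict = {}
            for ci, c in enumerate(rmol.components):
                r_by_name.setdefault(c.name, []).append(ci)
            p_by_name: dict = {}
            for ci, c in enumerate(pmol.components):
                p_by_name.setdefault(c.name, []).append(ci)
            if sorted(r_by_name) != sorted(p_by_name) or any(
                    len(r_by_name[n]) != len(p_by_name[n]) for n in r_by_name):
                raise ModelError(
                    f"rule {self.name}: molecule {rmol.name} lists different "
                    f"components on the two sides")
            for n, rcis in r_by_name.items():
                for rci, pci in zip(rcis, p_by_name[n]):
                    comp_corr[(ploc, pci)] = (rloc, rci)
                    rc = rmol.components[rci]
                    pc = pmol.components[pci]
                    if (rc.state or None) != (pc.state or None):
                        if pc.state is None:
                            raise ModelError(
                                f"rule {self.name}: state of {rmol.name}.{n} "
                                "erased on product side")
                        ops.append(Transformation(
                            "state", rloc + (rci,), pc.state))
                    if rc.bond in (WILD_BOUND, WILD_ANY) or \
                       pc.bond in (WILD_BOUND, WILD_ANY):
                        if rc.bond != pc.bond:
                            raise ModelError(
                                f"rule {self.name}: wildcard bond of "
                                f"{rmol.name}.{n} modified")

        # bond edge sets on each side, in reactant-locus coordinates
        def r_edges():
            edges = set()
            for slot, pat in enumerate(self.reactants):
                for (mi, ci), (mj, cj) in pat.partner_map().items():
                    a = (slot, mi, ci)
                    b = (slot, mj, cj)
                    edges.add(frozenset((a, b)))
            return edges

        def p_edges():
            edges = set()
            for pi, pat in enumerate(self.products):
                for (mi, ci), (mj, cj) in pat.partner_map().items():
                    ends = []
                    for (m, c) in ((mi, ci), (mj, cj)):
                        ploc = (pi, m)
                        if self.alignment[ploc] is None:
                            ends.append(("new", new_index[ploc], c))
                        else:
                            ends.append(comp_corr[(ploc, c)] + ())
                    # comp_corr values are (rloc, rci); flatten
                    flat = []
                    for e in ends:
                        if e[0] == "new":
                            flat.append(e)
                        else:
                            (rloc, rci) = e
                            flat.append(rloc + (rci,))
                    edges.add(frozenset(flat))
            return edges

        re_, pe_ = r_edges(), p_edges()
        # edges lost because a molecule is deleted are implicit
        deleted_mols = {t.args[0] for t in ops if t.kind == "delmol"}
        for e in re_ - pe_:
            if any(end[:2] in deleted_mols for end in e if end[0] != "new"):
                continue
            a, b = sorted(e, key=repr)
            ops.append(Transformation("delbond", a, b))
        for e in pe_ - re_:
            a, b = sorted(e, key=repr)
            ops.append(Transformation("addbond", a, b))

        mols_only = [m for _, m in new_molecules]
        return ops, mols_only

    # -- classification ------------------------------------------------------

    @property
    def molecularity(self):
        return len(self.reactants)

    def population_slots(self):
        out = []
        for i, pat in enumerate(self.reactants):
            if len(pat.molecules) == 1 and pat.molecules[0].is_population:
                out.append(i)
        return out

    def classify(self):
        pop = self.population_slots()
        if not self.reactants:
            return "particle"
        if len(pop) == len(self.reactants):
            return "population"
        if pop:
            return "mixed"
        return "particle"

    # -- symmetry ------------------------------------------------------------

    @property
    def symmetry(self) -> int:
        if self._symmetry is None:
            self._symmetry = symmetry_factor(self)
        return self._symmetry

    # -- application ---------------------------------------------------------

    def apply(self, complexes, matches, with_origins=False):
        """Apply the rule to concrete reactant complexes.

        ``complexes``/``matches`` are parallel to the structured reactant
        slots (population slots excluded — pass None there).  Returns the
        list of product complexes (connected SiteGraphs); with
        ``with_origins`` each product comes with a parallel list of
        ``("r", slot, mol_index)`` / ``("n", new_index)`` origins.
        """
        offset = {}
        origins = []
        work_molecules = []
        bond_relabel = {}
        next_bond = [1]

        for slot, pat in enumerate(self.reactants):
            if slot in set(self.population_slots()):
                continue
            cx = complexes[slot]
            if cx is None:
                raise ModelError(f"rule {self.name}: missing complex for slot {slot}")
            offset[slot] = len(work_molecules)
            for mi, mol in enumerate(cx.molecules):
                m = mol.copy()
                for c in m.components:
                    if isinstance(c.bond, int):
                        key = (slot, c.bond)
                        if key not in bond_relabel:
                            bond_relabel[key] = next_bond[0]
                            next_bond[0] += 1
                        c.bond = bond_relabel[key]
                work_molecules.append(m)
                origins.append(("r", slot, mi))

        def resolve(locus):
            if locus[0] == "new":
                raise AssertionError
            (slot, pmi, pci) = locus
            m = matches[slot]
            (tmi, tci) = m.comp_map[(pmi, pci)]
            return offset[slot] + tmi, tci

        pop_slots = set(self.population_slots())
        deleted = set()

        # synthesized molecules appended after reactant copies
        new_offset = len(work_molecules)
        new_bond_map = {}
        for k, mol in enumerate(self.new_molecules):
            m = mol.copy()
            for c in m.components:
                if isinstance(c.bond, int):
                    # internal new-new bonds will be rewired via addbond ops;
                    # clear and rebuild to keep labels unique
                    c.bond = None
            work_molecules.append(m)
            origins.append(("n", k))
            new_bond_map[k] = new_offset + k

        def resolve_end(end):
            if end[0] == "new":
                return new_bond_map[end[1]], end[2]
            return resolve(end)

        for op in self.ops:
            if op.kind == "delmol":
                (slot, pmi) = op.args[0]
                if slot in pop_slots:
                    continue  # handled by the caller (counter decrement)
                m = matches[slot]
                deleted.add(offset[slot] + m.mol_map[pmi])
            elif op.kind == "state":
                locus, new_state = op.args
                if locus[0] in pop_slots:
                    continue
                (wmi, wci) = resolve(locus)
                work_molecules[wmi].components[wci].state = new_state
            elif op.kind == "delbond":
                a, b = op.args
                if a[0] in pop_slots or b[0] in pop_slots:
                    continue
                (ami, aci) = resolve(a)
                (bmi, bci) = resolve(b)
                ca = work_molecules[ami].components[aci]
                cb = work_molecules[bmi].components[bci]
                if not isinstance(ca.bond, int) or ca.bond != cb.bond:
                    raise ModelError(
                        f"rule {self.name}: stale match (bond to delete is absent)")
                ca.bond = None
                cb.bond = None
            elif op.kind == "addbond":
                a, b = op.args
                if (a[0] in pop_slots and a[0] != "new") or \
                   (b[0] in pop_slots and b[0] != "new"):
                    continue
                (ami, aci) = resolve_end(a)
                (bmi, bci) = resolve_end(b)
                ca = work_molecules[ami].components[aci]
                cb = work_molecules[bmi].components[bci]
                if ca.bond is not None or cb.bond is not None:
                    raise ModelError(
                        f"rule {self.name}: adding a bond to a bound endpoint")
                ca.bond = next_bond[0]
                cb.bond = next_bond[0]
                next_bond[0] += 1
            else:
                raise AssertionError(op.kind)

        # drop deleted molecules and bonds into them
        keep = [i for i in range(len(work_molecules)) if i not in deleted]
        dangling = set()
        for i in deleted:
            for c in work_molecules[i].components:
                if isinstance(c.bond, int):
                    dangling.add(c.bond)
        final = []
        final_origins = []
        for i in keep:
            m = work_molecules[i]
            for c in m.components:
                if isinstance(c.bond, int) and c.bond in dangling:
                    c.bond = None
            final.append(m)
            final_origins.append(origins[i])
        whole = SiteGraph(final)
        comps = whole.component_indices()
        graphs = [whole.subgraph(ix) for ix in comps]
        if with_origins:
            return graphs, [[final_origins[i] for i in ix] for ix in comps]
        return graphs

    # -- serialization -------------------------------------------------------

    def to_string(self):
        lhs = " + ".join(p.to_string() for p in self.reactants) or "0"
        rhs = " + ".join(p.to_string() for p in self.products) or "0"
        rate = self.rate_name or repr(self.rate)
        return f"{self.name}: {lhs} -> {rhs}  {rate}"

    def __repr__(self):
        return f"Rule({self.to_string()!r})"


# ---------------------------------------------------------------------------
# Symmetry factor
# ---------------------------------------------------------------------------

def _strict_component_ok(pc, tc):
    if pc.name != tc.name or (pc.state or None) != (tc.state or None):
        return False
    pb, tb = pc.bond, tc.bond
    if isinstance(pb, int):
        return isinstance(tb, int)
    return pb == tb or (pb is None and tb is None)


def _pattern_automorphisms(union: SiteGraph, blocks):
    """Self-bijections of the reactant union preserving exact component
    attributes, bond structure, and the pattern-block partition."""
    out = []
    for m in _strict_matches(union, union):
        # bijection check: injective map of equal-size graphs with full
        # component coverage
        if any(len(union.molecules[i].components) !=
               len(union.molecules[j].components)
               for i, j in enumerate(m.mol_map)):
            continue
        # block preservation (up to permutation of blocks)
        img = {}
        ok = True
        for i, j in enumerate(m.mol_map):
            bi, bj = blocks[i], blocks[j]
            if bi in img and img[bi] != bj:
                ok = False
                break
            img[bi] = bj
        if ok and len(set(img.values())) == len(img):
            out.append(m)
    return out


def _strict_matches(pattern, target):
    """find_matches but with exact (non-wildcard-semantics) component equality."""
    from . import sitegraph as sg
    saved = sg._component_ok
    sg._component_ok = _strict_component_ok
    try:
        return find_matches(pattern, target)
    finally:
        sg._component_ok = saved


def symmetry_factor(rule: Rule) -> int:
    """Number of reactant-side automorphisms (including permutations of
    identical reactant patterns) that leave the transformation unchanged.

    Divides the raw embedding-tuple count so that each physically distinct
    event is counted once in propensities and reaction multiplicities.
    """
    union_mols = []
    blocks = []
    relabel_base = 0
    gmap = {}  # (slot, mi) -> global index
    for slot, pat in enumerate(rule.reactants):
        pat = pat.copy()
        shift = {}
        for mi, mol in enumerate(pat.molecules):
            for c in mol.components:
                if isinstance(c.bond, int):
                    if c.bond not in shift:
                        relabel_base += 1
                        shift[c.bond] = relabel_base
                    c.bond = shift[c.bond]
            gmap[(slot, mi)] = len(union_mols)
            union_mols.append(mol)
            blocks.append(slot)
    union = SiteGraph(union_mols)
    inv_g = {v: k for k, v in gmap.items()}

    def op_key(op, sigma_mol, sigma_comp):
        def map_locus(locus):
            if locus[0] == "new":
                return locus
            (slot, mi, ci) = locus
            g = gmap[(slot, mi)]
            (g2, ci2) = sigma_comp[(g, ci)]
            (slot2, mi2) = inv_g[g2]
            return (slot2, mi2, ci2)

        if op.kind == "delmol":
            (slot, mi) = op.args[0]
            g2 = sigma_mol[gmap[(slot, mi)]]
            return ("delmol", inv_g[g2])
        if op.kind == "state":
            return ("state", map_locus(op.args[0]), op.args[1])
        if op.kind in ("delbond", "addbond"):
            a = map_locus(op.args[0])
            b = map_locus(op.args[1])
            return (op.kind, tuple(sorted((a, b), key=repr)))
        raise AssertionError(op.kind)

    identity_keys = {op_key(op, {g: g for g in range(len(union_mols))},
                            {(g, ci): (g, ci)
                             for g in range(len(union_mols))
                             for ci in range(len(union_mols[g].components))})
                     for op in rule.ops}

    count = 0
    for aut in _pattern_automorphisms(union, blocks):
        sigma_mol = {i: j for i, j in enumerate(aut.mol_map)}
        sigma_comp = {(pmi, pci): tv for (pmi, pci), tv in aut.comp_map.items()}
        keys = {op_key(op, sigma_mol, sigma_comp) for op in rule.ops}
        if keys == identity_keys:
            count += 1
    return max(count, 1)


# ---------------------------------------------------------------------------
# Population maps
# ---------------------------------------------------------------------------

class PopulationMap:
    """Maps a structured species to an unstructured population counter."""

    __slots__ = ("structured", "unstructured_name", "k_lump")

    def __init__(self, structured: SiteGraph, unstructured_name: str,
                 k_lump: float):
        if k_lump <= 0:
            raise ModelError("lumping rate constant must be positive")
        self.structured = structured
        self.unstructured_name = unstructured_name
        self.k_lump = float(k_lump)

    def to_string(self):
        return (f"{self.structured.to_string()} -> "
                f"{self.unstructured_name}()  {self.k_lump:g}")


# ---------------------------------------------------------------------------
# Observables
# ---------------------------------------------------------------------------

class Observable:
    """Named readout: Molecules sums embeddings, Species counts complexes."""

    __slots__ = ("kind", "name", "patterns", "counter_terms")

    def __init__(self, kind, name, patterns, counter_terms=None):
        if kind not in ("Molecules", "Species"):
            raise ModelError(f"unknown observable type {kind}")
        self.kind = kind
        self.name = name
        self.patterns = list(patterns)
        # (population name, coefficient) pairs added by PNE rewriting
        self.counter_terms = list(counter_terms or [])


# ---------------------------------------------------------------------------
# The model document
# ---------------------------------------------------------------------------

class ModelDocument:
    def __init__(self):
        self.parameters: dict = {}
        self.molecule_types: dict = {}
        self.seeds: list = []          # (SiteGraph, count)
        self.pop_seeds: list = []      # (population name, count) — hybrid models
        self.observables: list = []
        self.rules: list = []
        self.population_maps: list = []
        self.config: dict = {}

    # -- validation ----------------------------------------------------------

    def _check_molecule(self, mol: Molecule, concrete: bool, where: str):
        mt = self.molecule_types.get(mol.name)
        if mt is None:
            raise ModelError(f"{where}: undeclared molecule type {mol.name}")
        declared: dict = {}
        for n, _ in mt.components:
            declared[n] = declared.get(n, 0) + 1
        used: dict = {}
        for c in mol.components:
            used[c.name] = used.get(c.name, 0) + 1
            if c.name not in declared:
                raise ModelError(
                    f"{where}: undeclared component {mol.name}.{c.name}")
            states = mt.states_for(c.name)
            if c.state is not None and (not states or c.state not in states):
                raise ModelError(
                    f"{where}: undeclared state {mol.name}.{c.name}~{c.state}")
            if concrete:
                if c.bond in (WILD_BOUND, WILD_ANY):
                    raise ModelError(f"{where}: wildcard in concrete species")
                if states and c.state is None:
                    raise ModelError(
                        f"{where}: unresolved state {mol.name}.{c.name}")
        for n, k in used.items():
            if k > declared[n]:
                raise ModelError(
                    f"{where}: component {mol.name}.{n} used {k}x, declared "
                    f"{declared[n]}x")
        if concrete and sum(used.values()) != sum(declared.values()):
            raise ModelError(
                f"{where}: concrete molecule {mol.name} omits components")

    def check_pattern(self, graph: SiteGraph, where: str):
        graph.validate_bonds()
        for mol in graph.molecules:
            self._check_molecule(mol, concrete=False, where=where)

    def check_species(self, graph: SiteGraph, where: str):
        graph.validate_bonds()
        if not graph.is_connected():
            raise ModelError(f"{where}: species must be connected")
        for mol in graph.molecules:
            self._check_molecule(mol, concrete=True, where=where)

    def validate(self):
        for i, (g, _) in enumerate(self.seeds):
            self.check_species(g, f"seed {i}")
        for r in self.rules:
            for j, p in enumerate(r.reactants):
                self.check_pattern(p, f"rule {r.name} reactant {j}")
            for j, p in enumerate(r.products):
                self.check_pattern(p, f"rule {r.name} product {j}")
        for o in self.observables:
            for p in o.patterns:
                self.check_pattern(p, f"observable {o.name}")
        seen_labels = []
        for pm in self.population_maps:
            self.check_species(pm.structured, "population map")
            mt = self.molecule_types.get(pm.unstructured_name)
            if mt is None or not mt.is_population:
                raise ModelError(
                    f"population map target {pm.unstructured_name} is not a "
                    "declared population molecule type")
            lab = canonical_label(pm.structured)
            if lab in seen_labels:
                raise ModelError(
                    f"two population maps share the structured species {lab}")
            seen_labels.append(lab)
        return self

    # -- queries --------------------------------------------------------------

    def is_fully_specified_species(self, graph: SiteGraph) -> bool:
        """True if graph is a complete, connected, wildcard-free species."""
        try:
            self.check_species(graph, "query")
        except ModelError:
            return False
        return True


def species_equals_pattern(model: ModelDocument, pattern: SiteGraph,
                           species: SiteGraph) -> bool:
    """True iff the pattern is itself a fully specified species isomorphic
    to ``species`` (the PNE step-1 self-match discard test)."""
    if not model.is_fully_specified_species(pattern):
        return False
    return isomorphic(pattern, species)
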