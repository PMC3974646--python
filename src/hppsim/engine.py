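"""Population-adapted network-free stochastic simulation (the HPP engine).

The engine is a particle-based variant of Gillespie's direct method.  The
system state is a collection of explicit molecular complexes (particles,
population 1 each) plus a counter table for unstructured population
species.  The propensity of rule ``r`` with rate ``k``, symmetry factor
``s`` and reactant patterns ``j = 1..m`` is::

    a_r = (k / s) * prod_j sum_k p_k * M_jk

where ``p_k`` is the population of complex ``k`` (1 for particles) and
``M_jk`` the number of embeddings of pattern ``j`` into ``k`` (0 or 1 when
``k`` is an unstructured population species).  With no population species
this reduces to the standard network-free propensity; with everything
lumped it reduces to the network-based SSA propensity.

Event loop randomness is consumed in a fixed, documented order per event:
(1) exponential waiting time, (2) rule selection, (3) per-slot reactant
selection (a population species is taken deterministically; particles are
drawn uniformly among matches via bounded rejection sampling), (4) the
symmetric-population rejection draw.  Identical (model, seed) pairs give
bit-identical trajectories.

Null events — same-complex bimolecular selections and symmetric-population
rejections — advance time but are excluded from firing counts.
Population-mapping rule firings are counted separately so they can be
subtracted in cross-engine comparisons.
"""

from __future__ import annotations

import itertools

import numpy as np

from .sitegraph import SiteGraph, Molecule, Component, canonical_form
from .model import ModelDocument, ModelError, Rule
from .network import Trajectory


class EngineError(RuntimeError):
    pass


class ParticleCapError(EngineError):
    """Runaway aggregate growth beyond the configured particle cap."""


# ---------------------------------------------------------------------------
# Engine molecules: mutable, pointer-bonded
# ---------------------------------------------------------------------------

class EMol:
    __slots__ = ("uid", "name", "cnames", "states", "bonds", "complex_id",
                 "alive")
    _next_uid = itertools.count()

    def __init__(self, name, cnames, states):
        self.uid = next(EMol._next_uid)   # deterministic ordering key
        self.name = name
        self.cnames = cnames          # tuple of component names
        self.states = states          # list of state strings or None
        self.bonds = [None] * len(cnames)   # None or (EMol, ci)
        self.complex_id = -1
        self.alive = True


# ---------------------------------------------------------------------------
# Compiled patterns
# ---------------------------------------------------------------------------

class CompiledPattern:
    """A reactant/observable pattern prepared for rooted matching.

    The pattern is traversed breadth-first from molecule 0; every later
    molecule is anchored through a bond to an earlier one (patterns must be
    connected).  ``eccentricity`` bounds how far a state change can sit
    from a root it affects."""

    __slots__ = ("graph", "key", "order", "root_name", "eccentricity",
                 "mol_plans")

    def __init__(self, graph: SiteGraph):
        from .sitegraph import _match_order
        self.graph = graph
        # sharing key: must preserve molecule/component ORDER, since rule
        # transformations address pattern loci by index — two isomorphic
        # patterns written with different component orders may not share
        # (only bond labels are normalized)
        self.key = graph.to_string(renumber=True)
        order = _match_order(graph)
        if any(anchor is None for (_, anchor) in order[1:]):
            raise ModelError(
                f"pattern {graph.to_string()} is disconnected; the engine "
                "requires connected reactant patterns")
        self.order = order
        self.root_name = graph.molecules[order[0][0]].name
        # eccentricity from molecule 0 over the bond graph
        n = len(graph.molecules)
        adj = graph.adjacency()
        dist = {order[0][0]: 0}
        frontier = [order[0][0]]
        while frontier:
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + 1
                        nxt.append(v)
            frontier = nxt
        self.eccentricity = max(dist.values()) if dist else 0
        # per-molecule component plan: list of (ci, name, state or None, bondkind)
        # bondkind: 0 free, 1 labelled, 2 wildcard-bound, 3 any
        self.mol_plans = []
        for mol in graph.molecules:
            plan = []
            for ci, c in enumerate(mol.components):
                if c.bond is None:
                    bk = 0
                elif isinstance(c.bond, int):
                    bk = 1
                elif c.bond == "+":
                    bk = 2
                else:
                    bk = 3
                plan.append((ci, c.name, c.state, bk))
            self.mol_plans.append(plan)


def _comp_candidates(plan_entry, tmol: EMol, used):
    (_, cname, cstate, bk) = plan_entry
    out = []
    for ti, tn in enumerate(tmol.cnames):
        if ti in used or tn != cname:
            continue
        if cstate is not None and tmol.states[ti] != cstate:
            continue
        b = tmol.bonds[ti]
        if bk == 0 and b is not None:
            continue
        if bk in (1, 2) and b is None:
            continue
        out.append(ti)
    return out


def reject_symmetric_null(p: int, rng) -> bool:
    """Null-event draw for a symmetric population reaction.

    When both slots of a symmetric rule select the same population species
    with count ``p``, the event must be rejected with probability ``1/p``
    so that a molecule cannot react with itself; the accepted rate becomes
    ``(k/s) * p^2 * (1 - 1/p)``, i.e. ``(k/2) p (p-1)`` for ``s = 2``.
    Returns True when the event is null."""
    if p < 1:
        raise EngineError("rejection drawn with empty population")
    return bool(rng.random() < 1.0 / p)


def match_rooted(cpat: CompiledPattern, root: EMol, collect=False):
    """Count (or collect) embeddings with pattern molecule ``order[0]``
    mapped onto ``root``.  Returns an int, or a list of comp-map dicts
    {(pmi, ci): (EMol, ti)} when ``collect`` is true."""
    graph = cpat.graph
    p_partners = graph.partner_map()
    order = cpat.order
    results = [] if collect else [0]
    mol_img: dict = {}
    comp_img: dict = {}
    used_mols = set()

    def try_mol(pos):
        if pos == len(order):
            if collect:
                results.append((dict(mol_img), dict(comp_img)))
            else:
                results[0] += 1
            return
        pmi, anchor = order[pos]
        if anchor is None:
            cand_mols = [(root, None)]
        else:
            (ami, aci, own_ci) = anchor
            (amol, ati) = comp_img[(ami, aci)]
            b = amol.bonds[ati]
            if b is None:
                return
            cand_mols = [(b[0], (own_ci, b[1]))]
        plan = cpat.mol_plans[pmi]
        pmol = graph.molecules[pmi]
        for (tmol, forced) in cand_mols:
            if tmol.name != pmol.name or id(tmol) in used_mols:
                continue

            def assign(k, used):
                if k == len(plan):
                    # bond closure check for pattern bonds into mapped region
                    for (ci, _, _, bk) in plan:
                        if bk == 1:
                            other = p_partners[(pmi, ci)]
                            if other in comp_img or (other[0] == pmi):
                                a = comp_img.get((pmi, ci))
                                b2 = comp_img.get(other)
                                if a is None or b2 is None:
                                    continue
                                bond = a[0].bonds[a[1]]
                                if bond is None or bond[0] is not b2[0] \
                                        or bond[1] != b2[1]:
                                    return
                    used_mols.add(id(tmol))
                    mol_img[pmi] = tmol
                    try_mol(pos + 1)
                    used_mols.discard(id(tmol))
                    del mol_img[pmi]
                    return
                entry = plan[k]
                ci = entry[0]
                if forced is not None and ci == forced[0]:
                    cands = [forced[1]] if forced[1] in \
                        _comp_candidates(entry, tmol, used) else []
                else:
                    cands = _comp_candidates(entry, tmol, used)
                for ti in cands:
                    comp_img[(pmi, ci)] = (tmol, ti)
                    assign(k + 1, used | {ti})
                    del comp_img[(pmi, ci)]

            assign(0, frozenset())

    try_mol(0)
    return results if collect else results[0]


# ---------------------------------------------------------------------------
# Weighted particle selection
# ---------------------------------------------------------------------------

class PatternState:
    """Per-pattern root bookkeeping: match counts by root molecule, their
    total, and an O(1) weighted sampler (bounded rejection)."""

    __slots__ = ("cpat", "counts", "items", "pos", "total", "maxc")

    def __init__(self, cpat):
        self.cpat = cpat
        self.counts = {}   # id(mol) -> count
        self.items = []    # list of EMol with count > 0
        self.pos = {}      # id(mol) -> index in items
        self.total = 0
        self.maxc = 1

    def set_count(self, mol: EMol, c: int):
        mid = id(mol)
        old = self.counts.get(mid, 0)
        if c == old:
            return
        self.total += c - old
        if c == 0:
            del self.counts[mid]
            i = self.pos.pop(mid)
            last = self.items.pop()
            if i < len(self.items):
                self.items[i] = last
                self.pos[id(last)] = i
        else:
            self.counts[mid] = c
            if old == 0:
                self.pos[mid] = len(self.items)
                self.items.append(mol)
            if c > self.maxc:
                self.maxc = c

    def sample_root(self, rng) -> EMol:
        n = len(self.items)
        while True:
            mol = self.items[int(rng.integers(n))]
            c = self.counts[id(mol)]
            if c >= self.maxc or rng.random() * self.maxc < c:
                return mol


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------

class SystemState:
    """Particle store plus population counters with match bookkeeping."""

    def __init__(self, model: ModelDocument, cap: int = 5_000_000):
        self.model = model
        self.cap = cap
        self.time = 0.0
        self.counters: dict = {}
        self.molecules: set = set()
        self.by_type: dict = {}          # name -> list of EMol (alive)
        self.by_type_pos: dict = {}      # id(mol) -> index
        self.complexes: dict = {}        # cid -> set of EMol
        self._next_cid = 0
        self._patterns: dict = {}        # key -> PatternState
        self._patterns_by_root: dict = {}  # type name -> [PatternState]
        self._rules = []
        self._rule_slots = []            # per rule: list of ("pop", name) | ("pat", PatternState)
        self._obs_plan = []

        self._setup_rules()
        self._max_ecc = max([ps.cpat.eccentricity
                             for ps in self._patterns.values()] + [0])
        self._seed()

    # -- setup ---------------------------------------------------------------

    def _register_pattern(self, graph: SiteGraph) -> PatternState:
        cpat = CompiledPattern(graph)
        ps = self._patterns.get(cpat.key)
        if ps is None:
            ps = PatternState(cpat)
            self._patterns[cpat.key] = ps
            self._patterns_by_root.setdefault(cpat.root_name, []).append(ps)
        return ps

    def _setup_rules(self):
        for nm, mt in self.model.molecule_types.items():
            if mt.is_population:
                self.counters.setdefault(nm, 0)
        for rule in self.model.rules:
            slots = []
            for pat in rule.reactants:
                if len(pat.molecules) == 1 and pat.molecules[0].is_population:
                    slots.append(("pop", pat.molecules[0].name))
                else:
                    if any(m.is_population for m in pat.molecules):
                        raise ModelError(
                            f"rule {rule.name}: population molecules cannot "
                            "mix with structured molecules in one pattern")
                    slots.append(("pat", self._register_pattern(pat)))
            self._rules.append(rule)
            self._rule_slots.append(slots)
        for obs in self.model.observables:
            pats = [self._register_pattern(p) for p in obs.patterns
                    if not (len(p.molecules) == 1
                            and p.molecules[0].is_population)]
            pops = [(p.molecules[0].name, 1.0) for p in obs.patterns
                    if len(p.molecules) == 1 and p.molecules[0].is_population]
            self._obs_plan.append((obs, pats, pops + list(obs.counter_terms)))

    def _seed(self):
        for name, n in self.model.pop_seeds:
            self.counters[name] = self.counters.get(name, 0) + int(round(n))
        for g, n in self.model.seeds:
            n = int(round(n))
            for _ in range(n):
                self.add_complex(g)

    # -- particle management -------------------------------------------------

    def n_particles(self):
        return len(self.molecules)

    def _new_cid(self):
        self._next_cid += 1
        return self._next_cid

    def _track(self, mol: EMol):
        self.molecules.add(mol)
        lst = self.by_type.setdefault(mol.name, [])
        self.by_type_pos[id(mol)] = len(lst)
        lst.append(mol)

    def _untrack(self, mol: EMol):
        self.molecules.discard(mol)
        lst = self.by_type[mol.name]
        i = self.by_type_pos.pop(id(mol))
        last = lst.pop()
        if i < len(lst):
            lst[i] = last
            self.by_type_pos[id(last)] = i

    def add_complex(self, graph: SiteGraph) -> list:
        """Instantiate a concrete SiteGraph as engine molecules."""
        mt = self.model.molecule_types
        mols = []
        for m in graph.molecules:
            t = mt[m.name]
            cnames = tuple(c.name for c in m.components)
            states = [c.state for c in m.components]
            em = EMol(m.name, cnames, states)
            mols.append(em)
        for (mi, ci), (mj, cj) in graph.partner_map().items():
            if mi < mj or (mi == mj and ci < cj):
                mols[mi].bonds[ci] = (mols[mj], cj)
                mols[mj].bonds[cj] = (mols[mi], ci)
        cid = self._new_cid()
        cset = set()
        for em in mols:
            em.complex_id = cid
            cset.add(em)
            self._track(em)
        self.complexes[cid] = cset
        if len(self.molecules) > self.cap:
            raise ParticleCapError(
                f"particle count exceeded cap ({self.cap})")
        self._recount(mols)
        return mols

    # -- match bookkeeping ---------------------------------------------------

    def _recount(self, mols):
        for mol in mols:
            plist = self._patterns_by_root.get(mol.name)
            if not plist:
                continue
            if not mol.alive:
                for ps in plist:
                    ps.set_count(mol, 0)
                continue
            for ps in plist:
                ps.set_count(mol, match_rooted(ps.cpat, mol))

    def _affected(self, touched, radius):
        """Molecules whose rooted counts may have changed: BFS out to the
        maximum pattern eccentricity over current bonds."""
        out = set(touched)
        frontier = list(touched)
        for _ in range(radius):
            nxt = []
            for mol in frontier:
                if not mol.alive:
                    continue
                for b in mol.bonds:
                    if b is not None and b[0] not in out:
                        out.add(b[0])
                        nxt.append(b[0])
            frontier = nxt
        return out

    # -- propensities ---------------------------------------------------------

    def propensities(self):
        out = np.empty(len(self._rules))
        for i, rule in enumerate(self._rules):
            a = rule.rate / rule.symmetry
            for kind, ref in self._rule_slots[i]:
                if kind == "pop":
                    a *= self.counters.get(ref, 0)
                else:
                    a *= ref.total
                if a == 0.0:
                    break
            out[i] = a
        return out

    def propensities_brute(self):
        """Debug cross-check: full recomputation from scratch."""
        out = np.empty(len(self._rules))
        for i, rule in enumerate(self._rules):
            a = rule.rate / rule.symmetry
            for kind, ref in self._rule_slots[i]:
                if kind == "pop":
                    a *= self.counters.get(ref, 0)
                else:
                    tot = 0
                    for mol in self.by_type.get(ref.cpat.root_name, []):
                        tot += match_rooted(ref.cpat, mol)
                    a *= tot
            out[i] = a
        return out

    # -- observables -----------------------------------------------------------

    def observable_values(self):
        vals = []
        for (obs, pats, pops) in self._obs_plan:
            if obs.kind == "Molecules":
                v = sum(ps.total for ps in pats)
                v += sum(w * self.counters.get(nm, 0) for (nm, w) in pops)
            else:  # Species: complexes matching as a whole
                v = 0.0
                for cid, cset in self.complexes.items():
                    hit = False
                    for ps in pats:
                        for mol in cset:
                            if mol.name == ps.cpat.root_name and \
                                    match_rooted(ps.cpat, mol):
                                hit = True
                                break
                        if hit:
                            break
                    if hit:
                        v += 1.0
                v += sum(w * self.counters.get(nm, 0) for (nm, w) in pops)
            vals.append(v)
        return vals

    # -- snapshots -------------------------------------------------------------

    def complex_graphs(self):
        """Current particle complexes as concrete SiteGraphs."""
        out = []
        for cid, cset in self.complexes.items():
            out.append(_to_sitegraph(cset))
        return out

    def complex_compositions(self):
        """(multiset of molecule names) per particle complex — cheap summary
        for cluster/polymer statistics."""
        out = []
        for cid, cset in self.complexes.items():
            comp: dict = {}
            for mol in cset:
                comp[mol.name] = comp.get(mol.name, 0) + 1
            out.append(comp)
        return out

    # -- firing ----------------------------------------------------------------

    def fire(self, rule_i: int, rng):
        """Select reactants for rule ``rule_i`` and apply it.

        Returns "fired", "null" (same-complex or symmetric rejection)."""
        rule = self._rules[rule_i]
        slots = self._rule_slots[rule_i]

        chosen_pops = []
        chosen_roots = []
        for kind, ref in slots:
            if kind == "pop":
                chosen_pops.append(ref)
                chosen_roots.append(None)
            else:
                chosen_roots.append(ref.sample_root(rng))
                chosen_pops.append(None)

        # same-complex bimolecular selections are null (intermolecular rule)
        cids = [m.complex_id for m in chosen_roots if m is not None]
        if len(cids) != len(set(cids)):
            return "null"
        # symmetric-population rejection: two slots on one counter species
        seen: dict = {}
        for nm in chosen_pops:
            if nm is not None:
                seen[nm] = seen.get(nm, 0) + 1
        for nm, k in seen.items():
            if k == 2:
                if reject_symmetric_null(self.counters[nm], rng):
                    return "null"
            elif k > 2:
                p = self.counters[nm]
                for j in range(1, k):
                    if rng.random() >= (p - j) / p:
                        return "null"

        # choose one embedding per structured slot, uniformly
        embeddings = []
        for (kind, ref), root in zip(slots, chosen_roots):
            if kind == "pop":
                embeddings.append(None)
                continue
            maps = match_rooted(ref.cpat, root, collect=True)
            if not maps:
                raise EngineError("bookkeeping out of sync: no match at root")
            embeddings.append(maps[int(rng.integers(len(maps)))])
            # embeddings are (molecule map, component map) pairs

        self._apply(rule, slots, embeddings, chosen_pops)
        return "fired"

    def _apply(self, rule: Rule, slots, embeddings, chosen_pops):
        pop_slots = set(rule.population_slots())
        radius = max([ps.cpat.eccentricity for (k, ps) in slots
                      if k == "pat"] + [0])
        radius = max(radius, self._max_ecc)

        touched = set()
        for emb in embeddings:
            if emb:
                for mol in emb[0].values():
                    touched.add(mol)
        pre_affected = self._affected(touched, radius)

        def locus(end):
            (slot, pmi, pci) = end
            return embeddings[slot][1][(pmi, pci)]

        new_mols = []
        dead = []
        for k, molp in enumerate(rule.new_molecules):
            if molp.is_population:
                new_mols.append(("pop", molp.name))
                continue
            mt = self.model.molecule_types[molp.name]
            cnames = tuple(c.name for c in molp.components)
            states = [c.state for c in molp.components]
            em = EMol(molp.name, cnames, states)
            new_mols.append(("mol", em))

        bonds_added = []
        bonds_deleted = []
        for op in rule.ops:
            if op.kind == "state":
                (slot, pmi, pci) = op.args[0]
                if slot in pop_slots:
                    continue
                (mol, ti) = locus(op.args[0])
                mol.states[ti] = op.args[1]
                touched.add(mol)
            elif op.kind == "delbond":
                a, b = op.args
                if a[0] in pop_slots or b[0] in pop_slots:
                    continue
                (ma, ta) = locus(a)
                (mb, tb) = locus(b)
                if ma.bonds[ta] is None or ma.bonds[ta][0] is not mb:
                    raise EngineError(f"rule {rule.name}: stale bond")
                ma.bonds[ta] = None
                mb.bonds[tb] = None
                bonds_deleted.append((ma, mb))
                touched.add(ma)
                touched.add(mb)
            elif op.kind == "addbond":
                ends = []
                skip = False
                for e in op.args:
                    if e[0] == "new":
                        ref = new_mols[e[1]]
                        if ref[0] == "pop":
                            skip = True
                            break
                        ends.append((ref[1], e[2]))
                    else:
                        if e[0] in pop_slots:
                            skip = True
                            break
                        ends.append(locus(e))
                if skip:
                    continue
                (ma, ta), (mb, tb) = ends
                if ma.bonds[ta] is not None or mb.bonds[tb] is not None:
                    raise EngineError(
                        f"rule {rule.name}: adding bond to bound endpoint")
                ma.bonds[ta] = (mb, tb)
                mb.bonds[tb] = (ma, ta)
                bonds_added.append((ma, mb))
                touched.add(ma)
                touched.add(mb)
            elif op.kind == "delmol":
                (slot, pmi) = op.args[0]
                if slot in pop_slots:
                    continue
                dead.append(embeddings[slot][0][pmi])

        # population counter updates
        for slot in pop_slots:
            nm = chosen_pops[slot]
            self.counters[nm] -= 1
            if self.counters[nm] < 0:
                raise EngineError(f"counter {nm} went negative")
        for ref in new_mols:
            if ref[0] == "pop":
                self.counters[ref[1]] = self.counters.get(ref[1], 0) + 1

        # delete molecules: unlink bonds, mark dead
        for mol in dead:
            for ci, b in enumerate(mol.bonds):
                if b is not None:
                    (other, oci) = b
                    other.bonds[oci] = None
                    bonds_deleted.append((mol, other))
                    touched.add(other)
                mol.bonds[ci] = None
            mol.alive = False
            touched.add(mol)

        # instantiate new molecules
        created = [ref[1] for ref in new_mols if ref[0] == "mol"]
        for em in created:
            cid = self._new_cid()
            em.complex_id = cid
            self.complexes[cid] = {em}
            self._track(em)
            touched.add(em)

        # complex bookkeeping: unions from added bonds, splits from deletions
        for (ma, mb) in bonds_added:
            self._union(ma, mb)
        for mol in dead:
            cset = self.complexes.get(mol.complex_id)
            if cset is not None:
                cset.discard(mol)
                if not cset:
                    del self.complexes[mol.complex_id]
            self._untrack(mol)
        for (ma, mb) in bonds_deleted:
            for m in (ma, mb):
                if m.alive:
                    self._resplit(m)

        if len(self.molecules) > self.cap:
            raise ParticleCapError(
                f"particle count exceeded cap ({self.cap})")

        post_affected = self._affected(touched, radius)
        self._recount(sorted(pre_affected | post_affected,
                             key=lambda m: m.uid))

    def _union(self, ma: EMol, mb: EMol):
        ca, cb = ma.complex_id, mb.complex_id
        if ca == cb:
            return
        sa, sb = self.complexes[ca], self.complexes[cb]
        if len(sa) < len(sb):
            (ca, cb), (sa, sb) = (cb, ca), (sb, sa)
        for m in sb:
            m.complex_id = ca
        sa.update(sb)
        del self.complexes[cb]

    def _resplit(self, mol: EMol):
        """Re-derive the connected component containing ``mol`` after a bond
        deletion; molecules left behind keep the old complex id."""
        cid = mol.complex_id
        cset = self.complexes[cid]
        seen = {mol}
        stack = [mol]
        while stack:
            m = stack.pop()
            for b in m.bonds:
                if b is not None and b[0] not in seen:
                    seen.add(b[0])
                    stack.append(b[0])
        if len(seen) == len(cset):
            return
        ncid = self._new_cid()
        for m in seen:
            m.complex_id = ncid
        self.complexes[ncid] = seen
        cset.difference_update(seen)


def _to_sitegraph(cset) -> SiteGraph:
    mols = sorted(cset, key=lambda m: m.uid)
    index = {id(m): i for i, m in enumerate(mols)}
    out = []
    bond_label = [0]
    labels: dict = {}
    for m in mols:
        comps = []
        for ci, cn in enumerate(m.cnames):
            b = m.bonds[ci]
            bond = None
            if b is not None:
                key = tuple(sorted(((id(m), ci), (id(b[0]), b[1]))))
                if key not in labels:
                    bond_label[0] += 1
                    labels[key] = bond_label[0]
                bond = labels[key]
            comps.append(Component(cn, m.states[ci], bond))
        out.append(Molecule(m.name, comps))
    return SiteGraph(out)


def simulate(model: ModelDocument, t_end: float, seed: int,
             n_steps: int = 100, cap: int = 5_000_000,
             max_events: int = 50_000_000, snapshot_times=None,
             snapshot_fn=None) -> Trajectory:
    """Network-free / hybrid stochastic trajectory of a model.

    Works on plain rule-based models (pure network-free run) and on PNE
    output (hybrid particle/population run); the two coincide when the
    model declares no population species."""
    rng = np.random.default_rng(seed)
    state = SystemState(model, cap=cap)

    grid = np.linspace(0.0, t_end, n_steps + 1)
    values = np.zeros((len(grid), len(model.observables)))
    out_i = 0
    snap_list = list(snapshot_times) if snapshot_times is not None else []
    snap_i = 0
    firings = 0
    mapping_firings = 0
    nulls = 0
    firings_by_rule: dict = {}
    t = 0.0

    events = 0
    while True:
        a = state.propensities()
        total = a.sum()
        if total <= 0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / total)
        while out_i < len(grid) and grid[out_i] <= t_next:
            values[out_i] = state.observable_values()
            out_i += 1
        while snap_i < len(snap_list) and snap_list[snap_i] <= t_next:
            if snapshot_fn is not None and snap_list[snap_i] <= t_end:
                snapshot_fn(snap_list[snap_i], state)
            snap_i += 1
        if out_i >= len(grid) or t_next > t_end:
            break
        t = t_next
        state.time = t
        u = rng.random() * total
        acc = 0.0
        ri = len(a) - 1
        for i, ai in enumerate(a):
            acc += ai
            if u < acc:
                ri = i
                break
        outcome = state.fire(ri, rng)
        if outcome == "fired":
            rule = state._rules[ri]
            if rule.is_population_map:
                mapping_firings += 1
            firings += 1
            firings_by_rule[rule.name] = firings_by_rule.get(rule.name, 0) + 1
        else:
            nulls += 1
        events += 1
        if events >= max_events:
            raise EngineError("event cap exceeded")

    names = [o.name for o in model.observables]
    return Trajectory(grid, names, values, firings, firings_by_rule,
                      mapping_firings=mapping_firings, null_events=nulls)
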