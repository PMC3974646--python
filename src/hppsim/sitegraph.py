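"""Site graphs: structured molecules, patterns, matching and canonical labels.

A site graph is a list of molecule instances, each carrying named components;
components hold an optional internal state and a bond slot.  The same data
structure represents both *patterns* (which may omit components and states and
may use bond wildcards) and *concrete* complexes/species (fully specified,
connected, no wildcards).

Bond slots take one of four values:

* ``None`` -- explicitly unbound,
* an ``int`` -- a bond label shared by exactly two components in the graph,
* ``"+"``  -- wildcard: bound to an unspecified partner (patterns only),
* ``"?"``  -- wildcard: bound or unbound (patterns only).

A component *omitted* from a pattern molecule is unconstrained, which is
distinct from ``"?"`` only in that it also allows the component to be absent
from the pattern entirely.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional, Union

Bond = Union[None, int, str]

WILD_BOUND = "+"
WILD_ANY = "?"


class SiteGraphError(ValueError):
    pass


class Component:
    __slots__ = ("name", "state", "bond")

    def __init__(self, name: str, state: Optional[str] = None, bond: Bond = None):
        self.name = name
        self.state = state
        self.bond = bond

    def copy(self) -> "Component":
        return Component(self.name, self.state, self.bond)

    def __repr__(self):
        return f"Component({self.to_string()!r})"

    def to_string(self) -> str:
        s = self.name
        if self.state is not None:
            s += "~" + self.state
        if self.bond is None:
            pass
        elif isinstance(self.bond, int):
            s += "!" + str(self.bond)
        else:
            s += "!" + self.bond
        return s


class Molecule:
    __slots__ = ("name", "components", "is_population")

    def __init__(self, name, components=None, is_population=False):
        self.name = name
        self.components = list(components or [])
        self.is_population = is_population

    def copy(self) -> "Molecule":
        return Molecule(self.name, [c.copy() for c in self.components],
                        self.is_population)

    def to_string(self) -> str:
        return f"{self.name}({','.join(c.to_string() for c in self.components)})"

    def __repr__(self):
        return f"Molecule({self.to_string()!r})"


class SiteGraph:
    """An ordered collection of molecules with bonds between components."""

    __slots__ = ("molecules",)

    def __init__(self, molecules=None):
        self.molecules = list(molecules or [])

    # -- construction helpers ------------------------------------------------

    def copy(self) -> "SiteGraph":
        return SiteGraph([m.copy() for m in self.molecules])

    def __len__(self):
        return len(self.molecules)

    def __repr__(self):
        return f"SiteGraph({self.to_string()!r})"

    # -- bond structure ------------------------------------------------------

    def bond_endpoints(self) -> dict:
        """Map bond label -> list of (molecule index, component index)."""
        ends: dict = {}
        for mi, mol in enumerate(self.molecules):
            for ci, comp in enumerate(mol.components):
                if isinstance(comp.bond, int):
                    ends.setdefault(comp.bond, []).append((mi, ci))
        return ends

    def partner_map(self) -> dict:
        """Map (mi, ci) -> (mj, cj) for every labelled bond endpoint."""
        partners = {}
        for label, ends in self.bond_endpoints().items():
            if len(ends) != 2:
                raise SiteGraphError(
                    f"bond label {label} occurs {len(ends)} times (expected 2)")
            (a, b) = ends
            partners[a] = b
            partners[b] = a
        return partners

    def validate_bonds(self) -> None:
        self.partner_map()

    def adjacency(self) -> dict:
        """Molecule-level adjacency: mi -> set of neighbouring molecule indices."""
        adj = {mi: set() for mi in range(len(self.molecules))}
        for (mi, _), (mj, _) in self.partner_map().items():
            adj[mi].add(mj)
        return adj

    def is_connected(self) -> bool:
        n = len(self.molecules)
        if n <= 1:
            return True
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == n

    def component_indices(self) -> list:
        """Connected components as sorted lists of molecule indices."""
        n = len(self.molecules)
        adj = self.adjacency()
        seen = set()
        out = []
        for start in range(n):
            if start in seen:
                continue
            comp = [start]
            seen.add(start)
            stack = [start]
            while stack:
                for j in sorted(adj[stack.pop()]):
                    if j not in seen:
                        seen.add(j)
                        comp.append(j)
                        stack.append(j)
            out.append(sorted(comp))
        return out

    def connected_components(self) -> list:
        """Split into connected sub-graphs (new SiteGraph objects)."""
        return [self.subgraph(ix) for ix in self.component_indices()]

    def subgraph(self, mol_indices) -> "SiteGraph":
        keep = set(mol_indices)
        ends = self.bond_endpoints()
        crossing = {lab for lab, es in ends.items()
                    if any(mi not in keep for mi, _ in es)
                    and any(mi in keep for mi, _ in es)}
        if crossing:
            raise SiteGraphError(f"bonds {sorted(crossing)} cross the subgraph cut")
        return SiteGraph([self.molecules[i].copy() for i in mol_indices])

    # -- predicates ----------------------------------------------------------

    def has_wildcards(self) -> bool:
        return any(c.bond in (WILD_BOUND, WILD_ANY)
                   for m in self.molecules for c in m.components)

    def molecule_count(self) -> int:
        return len(self.molecules)

    # -- serialization -------------------------------------------------------

    def to_string(self, renumber: bool = True) -> str:
        """BNGL-style string.  Bond labels renumbered by first appearance."""
        if not renumber:
            return ".".join(m.to_string() for m in self.molecules)
        relab: dict = {}
        parts = []
        for mol in self.molecules:
            cparts = []
            for comp in mol.components:
                s = comp.name
                if comp.state is not None:
                    s += "~" + comp.state
                if isinstance(comp.bond, int):
                    if comp.bond not in relab:
                        relab[comp.bond] = len(relab) + 1
                    s += "!" + str(relab[comp.bond])
                elif comp.bond is not None:
                    s += "!" + comp.bond
                cparts.append(s)
            parts.append(f"{mol.name}({','.join(cparts)})")
        return ".".join(parts)


# ---------------------------------------------------------------------------
# Pattern matching
# ---------------------------------------------------------------------------

class Match:
    """An embedding of a pattern into a target graph.

    ``mol_map`` maps pattern molecule index -> target molecule index;
    ``comp_map`` maps (pattern mi, ci) -> (target mi, ci).  The embedding is
    injective and preserves molecule types, component names, specified states
    and bond structure (with BNGL wildcard semantics).
    """

    __slots__ = ("pattern", "target", "mol_map", "comp_map")

    def __init__(self, pattern, target, mol_map, comp_map):
        self.pattern = pattern
        self.target = target
        self.mol_map = mol_map
        self.comp_map = comp_map

    def __repr__(self):
        return f"Match(mol_map={self.mol_map})"


def _component_ok(pc: Component, tc: Component) -> bool:
    if pc.name != tc.name:
        return False
    if pc.state is not None and pc.state != tc.state:
        return False
    b = pc.bond
    if b is None:
        return tc.bond is None
    if b == WILD_BOUND:
        return isinstance(tc.bond, int)
    if b == WILD_ANY:
        return True
    # labelled bond: target must be bound; partner checked globally
    return isinstance(tc.bond, int)


def _match_order(pattern: SiteGraph):
    """BFS ordering of pattern molecules with bond anchors.

    Returns a list of (pmi, anchor) where anchor is None for seeds and
    otherwise a (earlier_pmi, earlier_ci, own_ci) triple through which the
    target molecule is forced.
    """
    n = len(pattern.molecules)
    partners = pattern.partner_map()
    order = []
    placed = set()
    for seed in range(n):
        if seed in placed:
            continue
        order.append((seed, None))
        placed.add(seed)
        queue = [seed]
        while queue:
            cur = queue.pop(0)
            for ci, comp in enumerate(pattern.molecules[cur].components):
                if (cur, ci) in partners:
                    (oj, cj) = partners[(cur, ci)]
                    if oj not in placed:
                        order.append((oj, (cur, ci, cj)))
                        placed.add(oj)
                        queue.append(oj)
    return order


def _molecule_component_maps(pmol: Molecule, tmol: Molecule,
                             forced: Optional[tuple] = None) -> Iterator[dict]:
    """All injective component maps pattern-molecule -> target-molecule.

    ``forced`` optionally pins pattern component index to a target index.
    Components are grouped by name; within a name class every injective
    assignment compatible with state/bond constraints is yielded (this is
    where automorphic duplicates of symmetric patterns come from).
    """
    by_name: dict = {}
    for ti, tc in enumerate(tmol.components):
        by_name.setdefault(tc.name, []).append(ti)
    groups = []  # (list of pattern ci, list of candidate target ci)
    pname_groups: dict = {}
    for pi, pc in enumerate(pmol.components):
        pname_groups.setdefault(pc.name, []).append(pi)
    for name, pids in pname_groups.items():
        tids = by_name.get(name, [])
        if len(tids) < len(pids):
            return
        groups.append((pids, tids))

    def rec(gi, acc):
        if gi == len(groups):
            yield dict(acc)
            return
        pids, tids = groups[gi]
        for perm in itertools.permutations(tids, len(pids)):
            ok = True
            for pi, ti in zip(pids, perm):
                if forced is not None and pi == forced[0] and ti != forced[1]:
                    ok = False
                    break
                if not _component_ok(pmol.components[pi], tmol.components[ti]):
                    ok = False
                    break
            if ok:
                yield from rec(gi + 1, acc + list(zip(pids, perm)))

    yield from rec(0, [])


def find_matches(pattern: SiteGraph, target: SiteGraph,
                 max_matches: Optional[int] = None) -> list:
    """Enumerate every embedding of ``pattern`` into ``target``.

    Automorphic duplicates are returned (per-embedding counting); ordering is
    deterministic (lexicographic in the BFS traversal of the pattern and the
    molecule order of the target).
    """
    matches: list = []
    if not pattern.molecules:
        return matches
    order = _match_order(pattern)
    t_partners = target.partner_map()
    p_partners = pattern.partner_map()
    n_t = len(target.molecules)

    mol_map: dict = {}
    comp_map: dict = {}
    used_t = set()

    def bonds_consistent(pmi) -> bool:
        # every pattern bond with both endpoints mapped must map onto a target bond
        for ci, comp in enumerate(pattern.molecules[pmi].components):
            key = (pmi, ci)
            if key in p_partners:
                other = p_partners[key]
                if other[0] in mol_map or other[0] == pmi:
                    a = comp_map.get(key)
                    b = comp_map.get(other)
                    if a is None or b is None:
                        continue
                    if t_partners.get(a) != b:
                        return False
        return True

    def rec(pos):
        if pos == len(order):
            matches.append(Match(pattern, target,
                                 tuple(mol_map[i] for i in range(len(pattern.molecules))),
                                 dict(comp_map)))
            return len(matches) == max_matches
        pmi, anchor = order[pos]
        pmol = pattern.molecules[pmi]
        if anchor is not None:
            (ami, aci, own_ci) = anchor
            tgt_end = t_partners.get(comp_map[(ami, aci)])
            if tgt_end is None:
                return False
            candidates = [tgt_end[0]]
            forced = (own_ci, tgt_end[1])
        else:
            candidates = range(n_t)
            forced = None
        for tmi in candidates:
            if tmi in used_t:
                continue
            tmol = target.molecules[tmi]
            if tmol.name != pmol.name:
                continue
            for cmap in _molecule_component_maps(pmol, tmol, forced):
                mol_map[pmi] = tmi
                used_t.add(tmi)
                for pi, ti in cmap.items():
                    comp_map[(pmi, pi)] = (tmi, ti)
                if bonds_consistent(pmi):
                    if rec(pos + 1):
                        return True
                for pi in cmap:
                    del comp_map[(pmi, pi)]
                del mol_map[pmi]
                used_t.discard(tmi)
        return False

    rec(0)
    return matches


def count_matches(pattern: SiteGraph, target: SiteGraph) -> int:
    return len(find_matches(pattern, target))


def identity_match(graph: SiteGraph) -> Match:
    """The identity self-embedding (the PNE self-match)."""
    comp_map = {(mi, ci): (mi, ci)
                for mi, mol in enumerate(graph.molecules)
                for ci in range(len(mol.components))}
    return Match(graph, graph, tuple(range(len(graph.molecules))), comp_map)


def automorphism_count(graph: SiteGraph) -> int:
    """Number of self-embeddings (graph must be matchable onto itself)."""
    return len(find_matches(graph, graph))


# ---------------------------------------------------------------------------
# Canonical labelling
# ---------------------------------------------------------------------------

def _bond_kind(bond) -> int:
    if bond is None:
        return 0
    if isinstance(bond, int):
        return 1
    return 2 if bond == WILD_BOUND else 3


def _initial_colors(graph: SiteGraph):
    colors = []
    for mol in graph.molecules:
        sig = (mol.name,
               tuple(sorted((c.name, c.state or "", _bond_kind(c.bond))
                            for c in mol.components)))
        colors.append(repr(sig))
    return colors


def _refine(graph: SiteGraph, colors, partners):
    """Stable neighbourhood refinement; colors are strings throughout."""
    n = len(graph.molecules)
    cur = list(colors)
    while True:
        sigs = []
        for mi in range(n):
            edges = []
            for ci, comp in enumerate(graph.molecules[mi].components):
                key = (mi, ci)
                if key in partners:
                    (mj, cj) = partners[key]
                    edges.append((comp.name, comp.state or "",
                                  cur[mj],
                                  graph.molecules[mj].components[cj].name))
            sigs.append((cur[mi], tuple(sorted(edges))))
        ranks = {c: i for i, c in enumerate(sorted(set(sigs)))}
        nxt = ["c%d" % ranks[c] for c in sigs]
        if _partition_of(cur) == _partition_of(nxt):
            return nxt
        cur = nxt


def _partition_of(colors):
    cells: dict = {}
    for i, c in enumerate(colors):
        cells.setdefault(c, []).append(i)
    return sorted(tuple(v) for v in cells.values())


def _label_from_order(graph: SiteGraph, order) -> str:
    pos = {mi: k for k, mi in enumerate(order)}
    partners = graph.partner_map()
    # canonical component order inside each molecule
    comp_orders = {}
    tie_groups = {}
    for mi in order:
        mol = graph.molecules[mi]
        keyed = []
        for ci, comp in enumerate(mol.components):
            key = (mi, ci)
            if key in partners:
                (mj, cj) = partners[key]
                pk = (1, pos[mj], graph.molecules[mj].components[cj].name)
            else:
                pk = (_bond_kind(comp.bond) if comp.bond is not None else 0,
                      -1, "")
            keyed.append(((comp.name, comp.state or "", pk), ci))
        keyed.sort(key=lambda t: t[0])
        comp_orders[mi] = [ci for _, ci in keyed]
        # ties: identical sort keys bonded into the same molecule position
        ties = {}
        for k, ci in keyed:
            ties.setdefault(k, []).append(ci)
        tie_groups[mi] = [v for v in ties.values() if len(v) > 1]

    def build(comp_orders_local) -> str:
        relab: dict = {}
        parts = []
        for mi in order:
            mol = graph.molecules[mi]
            cparts = []
            for ci in comp_orders_local[mi]:
                comp = mol.components[ci]
                s = comp.name
                if comp.state is not None:
                    s += "~" + comp.state
                if isinstance(comp.bond, int):
                    if comp.bond not in relab:
                        relab[comp.bond] = len(relab) + 1
                    s += "!" + str(relab[comp.bond])
                elif comp.bond is not None:
                    s += "!" + comp.bond
                cparts.append(s)
            parts.append(f"{mol.name}({','.join(cparts)})")
        return ".".join(parts)

    # resolve residual within-molecule ties (identical comps bonded to the
    # same partner molecule) by brute-force minimisation; tie classes are tiny
    tied = [(mi, g) for mi in order for g in tie_groups[mi]]
    if not tied:
        return build(comp_orders)
    best = None
    choices = [itertools.permutations(g) for _, g in tied]
    for combo in itertools.product(*choices):
        co = {mi: list(v) for mi, v in comp_orders.items()}
        for ((mi, g), perm) in zip(tied, combo):
            base = [i for i in co[mi] if i in g]
            repl = dict(zip(base, perm))
            co[mi] = [repl.get(i, i) for i in co[mi]]
        s = build(co)
        if best is None or s < best:
            best = s
    return best


def canonical_label(graph: SiteGraph) -> str:
    """Canonical string label; equal labels iff graphs are isomorphic.

    Iterative neighbourhood refinement with backtracking on ties
    (individualisation-refinement, minimum label over branches).  Requires a
    concrete graph: wildcards raise ``SiteGraphError`` (use
    :func:`canonical_form` for patterns).
    """
    for mol in graph.molecules:
        for comp in mol.components:
            if comp.bond in (WILD_BOUND, WILD_ANY):
                raise SiteGraphError("cannot canonicalize a pattern (wildcard bond)")
    return canonical_form(graph)


def canonical_form(graph: SiteGraph) -> str:
    """Canonical string of an arbitrary site graph, wildcards included.

    Same algorithm as :func:`canonical_label` without the concreteness
    check; used to compare patterns and to deduplicate derived rules."""
    partners = graph.partner_map()
    n = len(graph.molecules)
    if n == 0:
        return ""

    best: list = [None]

    def search(colors):
        colors = _refine(graph, colors, partners)
        cells: dict = {}
        for i, c in enumerate(colors):
            cells.setdefault(c, []).append(i)
        non_singleton = [v for v in sorted(cells.items()) if len(v[1]) > 1]
        if not non_singleton:
            order = [i for _, i in sorted((c, i) for i, c in enumerate(colors))]
            lab = _label_from_order(graph, order)
            if best[0] is None or lab < best[0]:
                best[0] = lab
            return
        # individualize within the first non-singleton cell
        _, members = non_singleton[0]
        for m in members:
            branched = list(colors)
            branched[m] = branched[m] + "*"
            search(branched)

    search(_initial_colors(graph))
    return best[0]


def isomorphic(a: SiteGraph, b: SiteGraph) -> bool:
    """Exact isomorphism test via mutual full-specification matching."""
    if len(a.molecules) != len(b.molecules):
        return False
    counts_a = sorted(m.name for m in a.molecules)
    counts_b = sorted(m.name for m in b.molecules)
    if counts_a != counts_b:
        return False
    for m in find_matches(a, b, max_matches=None):
        # injective + equal molecule count => bijective; with equal
        # per-molecule component counts the embedding is an isomorphism
        # (find_matches already enforces states and bond structure).
        if all(len(a.molecules[i].components) ==
               len(b.molecules[j].components)
               for i, j in enumerate(m.mol_map)):
            return True
    return False
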