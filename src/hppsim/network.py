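"""Reaction-network generation and network-based stochastic simulation.

``generate_network`` iteratively applies the rules of a model to the seed
species, canonicalizing and deduplicating every product, until a fixed point
is reached (or a species/iteration limit trips, since rule-based models can
encode infinite networks).  The resulting :class:`ReactionNetwork` is
simulated exactly with Gillespie's direct method in ``simulate_ssa`` and is
also the reference for the printed species/reaction-count checks.

Reaction accounting: each reaction is recorded once per generating rule and
reactant/product species multiset, with an integer ``multiplicity`` equal to
the number of embedding tuples that produce it.  The effective rate factor
is ``rate * multiplicity / symmetry``; propensities multiply this by
``n_i * n_j`` for distinct reactant species, ``n * (n - 1)`` for an
identical pair (ordered pairs — the symmetry factor already corrects the
double count), and ``n`` for unimolecular reactions.
"""

from __future__ import annotations

import itertools

import numpy as np

from .sitegraph import SiteGraph, canonical_label, find_matches
from .model import ModelDocument, ModelError, Rule


class NetworkLimitError(RuntimeError):
    """Raised when network generation hits a species or iteration limit."""


class Reaction:
    __slots__ = ("reactants", "products", "rate", "multiplicity",
                 "symmetry", "rule_name")

    def __init__(self, reactants, products, rate, multiplicity, symmetry,
                 rule_name):
        self.reactants = tuple(reactants)   # species indices, sorted
        self.products = tuple(products)     # species indices, sorted
        self.rate = rate
        self.multiplicity = multiplicity
        self.symmetry = symmetry
        self.rule_name = rule_name

    @property
    def rate_factor(self):
        return self.rate * self.multiplicity / self.symmetry

    def is_null(self):
        return self.reactants == self.products


class ReactionNetwork:
    def __init__(self):
        self.species_labels: list = []
        self.species_graphs: list = []
        self.initial_counts: list = []
        self.reactions: list = []
        self.observables: list = []   # (name, kind, coefficient vector)

    @property
    def n_species(self):
        return len(self.species_labels)

    @property
    def n_reactions(self):
        return len(self.reactions)

    def species_index(self, label):
        return self.species_labels.index(label)


def generate_network(model: ModelDocument, max_iterations: int = 100,
                     max_species: int = 50_000) -> ReactionNetwork:
    """Expand a rule-based model into its full reaction network.

    Raises :class:`NetworkLimitError` naming the limit if the expansion does
    not reach a fixed point within the given bounds.
    """
    if max_iterations <= 0 or max_species <= 0:
        raise ValueError("limits must be positive")
    net = ReactionNetwork()
    index: dict = {}

    def add_species(graph, count=0.0):
        lab = canonical_label(graph)
        if lab in index:
            return index[lab], False
        if len(index) >= max_species:
            raise NetworkLimitError(
                f"species limit exceeded (max_species={max_species}); the "
                "model may encode an infinite network")
        index[lab] = len(net.species_labels)
        net.species_labels.append(lab)
        net.species_graphs.append(graph)
        net.initial_counts.append(count)
        return index[lab], True

    for g, n in model.seeds:
        si, fresh = add_species(g.copy(), n)
        if not fresh:
            net.initial_counts[si] += n

    rules = [r for r in model.rules if not r.is_population_map]
    match_cache: dict = {}   # (rule_i, slot, species_i) -> match count > 0 list

    def matches_for(ri, slot, si):
        key = (ri, slot, si)
        if key not in match_cache:
            match_cache[key] = find_matches(
                rules[ri].reactants[slot], net.species_graphs[si])
        return match_cache[key]

    reaction_acc: dict = {}  # (rule_i, reactants sorted, products sorted) -> tuples
    new_species = list(range(net.n_species))
    iteration = 0
    while new_species:
        iteration += 1
        if iteration > max_iterations:
            raise NetworkLimitError(
                f"iteration limit exceeded (max_iterations={max_iterations})")
        frontier = set(new_species)
        n_known = net.n_species
        new_species = []
        for ri, rule in enumerate(rules):
            m = rule.molecularity
            # ordered species tuples with at least one frontier member,
            # all indices < n_known
            slots_candidates = []
            for slot in range(m):
                cands = [si for si in range(n_known)
                         if matches_for(ri, slot, si)]
                slots_candidates.append(cands)
            for combo in itertools.product(*slots_candidates):
                if not any(si in frontier for si in combo):
                    continue
                slot_matches = [matches_for(ri, slot, si)
                                for slot, si in enumerate(combo)]
                for mcombo in itertools.product(*slot_matches):
                    graphs = [net.species_graphs[si] for si in combo]
                    products = rule.apply(graphs, list(mcombo))
                    pidx = []
                    for pg in products:
                        si, fresh = add_species(pg)
                        if fresh:
                            new_species.append(si)
                        pidx.append(si)
                    key = (ri, tuple(sorted(combo)), tuple(sorted(pidx)))
                    reaction_acc[key] = reaction_acc.get(key, 0) + 1

    # multiplicity is the embedding-tuple count per labeled species
    # assignment; the ordered-pair propensity convention (n_i * n_j, or
    # n*(n-1) for an identical pair) together with rate/symmetry makes the
    # flux exact for symmetric rules as well.
    for (ri, rs, ps), tuples in sorted(reaction_acc.items()):
        rule = rules[ri]
        net.reactions.append(Reaction(rs, ps, rule.rate, tuples,
                                      rule.symmetry, rule.name))

    # precompute observable coefficient vectors
    for obs in model.observables:
        coef = np.zeros(net.n_species)
        for si, g in enumerate(net.species_graphs):
            v = 0.0
            for pat in obs.patterns:
                nm = len(find_matches(pat, g))
                if obs.kind == "Molecules":
                    v += nm
                else:
                    v += 1.0 if nm else 0.0
        # Species-kind observables count a complex once even if several
        # patterns hit it; recompute accordingly
            coef[si] = v
        if obs.kind == "Species":
            for si, g in enumerate(net.species_graphs):
                coef[si] = 1.0 if any(find_matches(p, g)
                                      for p in obs.patterns) else 0.0
        net.observables.append((obs.name, obs.kind, coef))
    return net


# ---------------------------------------------------------------------------
# Gillespie direct method
# ---------------------------------------------------------------------------

class Trajectory:
    """Sampled observables plus firing accounts (shared across engines)."""

    def __init__(self, times, observable_names, values, total_firings,
                 firings_by_rule, mapping_firings=0, null_events=0):
        self.times = np.asarray(times)
        self.observable_names = list(observable_names)
        self.values = np.asarray(values)
        self.total_firings = total_firings
        self.firings_by_rule = dict(firings_by_rule)
        self.mapping_firings = mapping_firings
        self.null_events = null_events

    @property
    def firings_excluding_mapping(self):
        return self.total_firings - self.mapping_firings

    def observable(self, name):
        return self.values[:, self.observable_names.index(name)]

    def to_gdat(self) -> str:
        header = "# time " + " ".join(self.observable_names)
        lines = [header]
        for i, t in enumerate(self.times):
            row = " ".join(f"{v:.6g}" for v in self.values[i])
            lines.append(f"{t:.6g} {row}")
        return "\n".join(lines) + "\n"


def simulate_ssa(network: ReactionNetwork, t_end: float, seed: int,
                 n_steps: int = 100, max_events: int = 50_000_000) -> Trajectory:
    """Exact direct-method trajectory of a fully enumerated network."""
    rng = np.random.default_rng(seed)
    counts = np.array([round(c) for c in network.initial_counts], dtype=np.int64)
    if (counts < 0).any():
        raise ValueError("negative initial count")

    rxns = network.reactions
    n_r = len(rxns)
    rate_factors = np.array([r.rate_factor for r in rxns])
    r1 = np.array([r.reactants[0] if len(r.reactants) > 0 else -1 for r in rxns])
    r2 = np.array([r.reactants[1] if len(r.reactants) > 1 else -1 for r in rxns])
    delta = np.zeros((n_r, network.n_species), dtype=np.int64)
    for i, r in enumerate(rxns):
        for si in r.reactants:
            delta[i, si] -= 1
        for si in r.products:
            delta[i, si] += 1

    grid = np.linspace(0.0, t_end, n_steps + 1)
    obs_mat = np.array([coef for (_, _, coef) in network.observables]) \
        if network.observables else np.zeros((0, network.n_species))
    values = np.zeros((len(grid), len(network.observables)))
    out_i = 0
    t = 0.0
    firings = 0
    firings_by_rule: dict = {}

    def propensities():
        a = rate_factors.copy()
        has1 = r1 >= 0
        a[has1] *= counts[r1[has1]]
        both = r2 >= 0
        same = both & (r1 == r2)
        diff = both & ~same
        a[diff] *= counts[r2[diff]]
        a[same] *= np.maximum(counts[r2[same]] - 1, 0)
        return a

    while True:
        a = propensities()
        total = a.sum()
        if total <= 0:
            t_next = np.inf
        else:
            t_next = t + rng.exponential(1.0 / total)
        while out_i < len(grid) and grid[out_i] <= t_next:
            if obs_mat.size:
                values[out_i] = obs_mat @ counts
            out_i += 1
        if out_i >= len(grid) or t_next > t_end:
            break
        t = t_next
        j = int(np.searchsorted(np.cumsum(a), rng.random() * total,
                                side="right"))
        j = min(j, n_r - 1)
        counts += delta[j]
        if (counts < 0).any():
            raise RuntimeError(
                f"negative species count after reaction {j} "
                f"(rule {rxns[j].rule_name}) — propensity logic error")
        firings += 1
        name = rxns[j].rule_name
        firings_by_rule[name] = firings_by_rule.get(name, 0) + 1
        if firings >= max_events:
            raise RuntimeError("SSA event cap exceeded")

    names = [n for (n, _, _) in network.observables]
    return Trajectory(grid, names, values, firings, firings_by_rule)


# ---------------------------------------------------------------------------
# Plain-text network file (.net-style)
# ---------------------------------------------------------------------------

def write_net(network: ReactionNetwork) -> str:
    out = ["begin species"]
    for i, lab in enumerate(network.species_labels):
        out.append(f"  {i + 1} {lab} {network.initial_counts[i]:.12g}")
    out.append("end species")
    out.append("begin reactions")
    for i, r in enumerate(network.reactions):
        rs = ",".join(str(x + 1) for x in r.reactants) or "0"
        ps = ",".join(str(x + 1) for x in r.products) or "0"
        out.append(f"  {i + 1} {rs} {ps} {r.rate:.12g} {r.multiplicity} "
                   f"{r.symmetry} # {r.rule_name}")
    out.append("end reactions")
    return "\n".join(out) + "\n"


def read_net(text: str) -> ReactionNetwork:
    from .bngl import parse_pattern
    net = ReactionNetwork()
    block = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("begin "):
            block = line[6:].strip()
            continue
        if line.startswith("end "):
            block = None
            continue
        parts = line.split()
        if block == "species":
            (_, lab, n0) = parts
            net.species_labels.append(lab)
            net.species_graphs.append(parse_pattern(lab))
            net.initial_counts.append(float(n0))
        elif block == "reactions":
            (_, rs, ps, rate, mult, sym) = parts
            reac = [int(x) - 1 for x in rs.split(",")] if rs != "0" else []
            prod = [int(x) - 1 for x in ps.split(",")] if ps != "0" else []
            net.reactions.append(Reaction(reac, prod, float(rate),
                                          int(mult), int(sym), "?"))
    return net
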