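import numpy as np
import pytest

from hppsim import read_model, generate_network
from hppsim.fixtures import fixture_text


@pytest.fixture(scope="session")
def receptor_model():
    return read_model(fixture_text("receptor_activation"))


@pytest.fixture(scope="session")
def receptor_network(receptor_model):
    return generate_network(receptor_model)


@pytest.fixture(scope="session")
def fceri_model():
    return read_model(fixture_text("fceri_gamma2"))


@pytest.fixture(scope="session")
def fceri_network(fceri_model):
    # ~20 s; shared by the species/reaction count check and the SSA runs
    return generate_network(fceri_model)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260918)


def random_complex(rng, n_mol_max=6):
    """A random concrete connected complex over three molecule types.

    Types: X(a,b,s~u~p), Y(a,a), Z(b).  Built as a random tree of bonds
    (X.a-Y.a and X.b-Z.b edges), states drawn uniformly.
    """
    from hppsim import SiteGraph, Molecule, Component

    n = int(rng.integers(1, n_mol_max + 1))
    mols = []
    kinds = []
    for i in range(n):
        k = int(rng.integers(0, 3)) if i else 0   # root is always X
        kinds.append(k)
        if k == 0:
            mols.append(Molecule("X", [
                Component("a"), Component("b"),
                Component("s", "u" if rng.random() < 0.5 else "p")]))
        elif k == 1:
            mols.append(Molecule("Y", [Component("a"), Component("a")]))
        else:
            mols.append(Molecule("Z", [Component("b")]))
    # connect molecule i>0 to a random earlier molecule at compatible sites
    bond = 0
    for i in range(1, n):
        tries = list(rng.permutation(i))
        placed = False
        for j in tries:
            for (ci, cj) in _compatible_sites(mols[i], mols[j]):
                bond += 1
                mols[i].components[ci].bond = bond
                mols[j].components[cj].bond = bond
                placed = True
                break
            if placed:
                break
        if not placed:
            return random_complex(rng, n_mol_max)   # resample
    return SiteGraph(mols)


def _compatible_sites(mi, mj):
    """Unbound (a,a) or (b,b) site pairs between two molecules."""
    out = []
    for ci, c in enumerate(mi.components):
        if c.bond is not None or c.name == "s":
            continue
        for cj, d in enumerate(mj.components):
            if d.bond is not None or d.name == "s":
                continue
            if c.name == d.name:
                out.append((ci, cj))
    return out


def sitegraph_to_networkx(g):
    """Convert for the brute-force isomorphism oracle (molecule-level
    multigraph with per-molecule component signatures encoded as node
    attributes plus edge site labels)."""
    import networkx as nx
    G = nx.MultiGraph()
    for i, mol in enumerate(g.molecules):
        free = tuple(sorted((c.name, c.state or "")
                            for c in mol.components if c.bond is None))
        G.add_node(i, name=mol.name, free=free)
    for label, ends in g.bond_endpoints().items():
        (mi, ci), (mj, cj) = ends
        names = tuple(sorted([
            (g.molecules[mi].name, g.molecules[mi].components[ci].name,
             g.molecules[mi].components[ci].state or ""),
            (g.molecules[mj].name, g.molecules[mj].components[cj].name,
             g.molecules[mj].components[cj].state or "")]))
        G.add_edge(mi, mj, sites=names)
    return G


def networkx_isomorphic(a, b):
    import networkx as nx
    return nx.is_isomorphic(
        sitegraph_to_networkx(a), sitegraph_to_networkx(b),
        node_match=lambda x, y: x == y,
        edge_match=lambda x, y: x == y)
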