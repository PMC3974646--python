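"""Rule application, symmetry factors, species/pattern equality."""

import numpy as np
import pytest

from hppsim import (read_model, parse_pattern, find_matches, Rule,
                    symmetry_factor, species_equals_pattern, canonical_label,
                    generate_network, simulate_ssa, Molecule, SiteGraph)
from hppsim.model import ModelError
from hppsim.sitegraph import identity_match

from conftest import sitegraph_to_networkx


def make_rule(name, lhs, rhs, rate=1.0):
    reactants = [parse_pattern(p) for p in lhs.split(" + ")]
    products = [parse_pattern(p) for p in rhs.split(" + ")] if rhs else []
    return Rule(name, reactants, products, rate)


def pop_rule(name, n_pops, products, rate=1.0):
    reactants = [SiteGraph([Molecule("pop_A", [], is_population=True)])
                 for _ in range(n_pops)]
    return Rule(name, reactants,
                [parse_pattern(p) for p in products], rate)


class TestApplyRule:
    def test_minimal_unbinding_splits_dimer(self):
        r = make_rule("u", "A(b!1).B(a!1)", "A(b) + B(a)")
        dimer = parse_pattern("A(b!5).B(a!5)")
        m = find_matches(r.reactants[0], dimer)[0]
        products = r.apply([dimer], [m])
        labels = sorted(p.to_string() for p in products)
        assert labels == ["A(b)", "B(a)"]

    def test_bond_deletion_yields_connected_components(self, rng):
        # rebuild-and-split oracle via networkx on a branched aggregate
        import networkx as nx
        agg = parse_pattern(
            "A(b!1,c!2).B(a!1,d!3).C(a!2).D(b!3,c!4).C(a!4)"
            .replace("C(a", "Cm(a").replace("D(b", "Dm(b"))
        r = make_rule("cut", "A(b!1).B(a!1)", "A(b) + B(a)")
        m = find_matches(r.reactants[0], agg)[0]
        products = r.apply([agg], [m])
        G = sitegraph_to_networkx(agg)
        # remove the A-B edge and compare component molecule-name multisets
        for (u, v, k, d) in list(G.edges(keys=True, data=True)):
            if {G.nodes[u]["name"], G.nodes[v]["name"]} == {"A", "B"} and \
                    {s[1] for s in d["sites"]} == {"a", "b"}:
                G.remove_edge(u, v, k)
                break
        expected = sorted(
            sorted(G.nodes[n]["name"] for n in comp)
            for comp in nx.connected_components(G))
        got = sorted(sorted(mol.name for mol in p.molecules)
                     for p in products)
        assert got == expected
        assert len(products) == 2

    def test_state_change_and_conservation(self):
        r = make_rule("p", "X(s~u)", "X(s~p)")
        target = parse_pattern("X(a!1,b,s~u).Y(a!1,a)")
        m = find_matches(r.reactants[0], target)[0]
        products = r.apply([target], [m])
        assert len(products) == 1
        assert sum(len(p.molecules) for p in products) == 2
        assert "s~p" in products[0].to_string()

    def test_molecule_deletion_removes_bonds(self):
        r = make_rule("deg", "B(a!1).A(b!1)", "A(b)")
        dimer = parse_pattern("B(a!1,c!2).A(b!1).C(b!2)"
                              .replace("C(b", "Cm(b"))
        m = find_matches(r.reactants[0], dimer)[0]
        products = r.apply([dimer], [m])
        names = sorted(p.to_string() for p in products)
        assert names == ["A(b)", "Cm(b)"]

    def test_add_bond_to_bound_endpoint_errors(self):
        r = make_rule("b", "A(b) + B(a)", "A(b!1).B(a!1)")
        a = parse_pattern("A(b)")
        b_bound = parse_pattern("B(a!1).B(a!1)")
        # force a stale match: claim B's bound site is free
        m_a = find_matches(r.reactants[0], a)[0]
        m_b = find_matches(parse_pattern("B(a!?)"), b_bound)[0]
        m_b.pattern = r.reactants[1]
        with pytest.raises(ModelError):
            r.apply([a, b_bound], [m_a, m_b])

    def test_random_firings_match_rebuild_oracle(self):
        # unbinding rule applied at random sites of random aggregates
        import networkx as nx
        rng = np.random.default_rng(3)
        from conftest import random_complex
        r = make_rule("cut", "X(a!1).Y(a!1)", "X(a) + Y(a)")
        tested = 0
        for _ in range(40):
            agg = random_complex(rng, n_mol_max=6)
            ms = find_matches(r.reactants[0], agg)
            if not ms:
                continue
            tested += 1
            m = ms[int(rng.integers(len(ms)))]
            products = r.apply([agg], [m])
            G = sitegraph_to_networkx(agg)
            (xm, _), (ym, _) = (m.comp_map[(0, 0)], m.comp_map[(1, 0)])
            # translate back: molecule indices of X and Y in the match
            xi, yi = m.mol_map[0], m.mol_map[1]
            removed = False
            for (u, v, k) in list(G.edges(keys=True)):
                if {u, v} == {xi, yi} and not removed:
                    d = G.get_edge_data(u, v, k)
                    if {s[0] for s in d["sites"]} == {"X", "Y"} and \
                            {s[1] for s in d["sites"]} == {"a"}:
                        G.remove_edge(u, v, k)
                        removed = True
            assert removed
            expected = sorted(sorted(G.nodes[n]["name"] for n in comp)
                              for comp in nx.connected_components(G))
            got = sorted(sorted(mol.name for mol in p.molecules)
                         for p in products)
            assert got == expected
        assert tested >= 10


class TestSymmetryFactor:
    @pytest.mark.parametrize("lhs,rhs,expected", [
        ("A(b) + B(a)", "A(b!1).B(a!1)", 1),
        ("A(a) + A(a)", "A(a!1).A(a!1)", 2),
        ("L(r,r,r) + R(l)", "L(r!1,r,r).R(l!1)", 2),
        ("L(r,r!+,r!+) + R(l)", "L(r!1,r!+,r!+).R(l!1)", 2),
        ("A(b!1).B(a!1)", "A(b) + B(a)", 1),
    ])
    def test_structured_rules(self, lhs, rhs, expected):
        assert symmetry_factor(make_rule("r", lhs, rhs)) == expected

    def test_identical_population_reactants(self):
        r = pop_rule("dim", 2, ["A(a!1).A(a!1)"])
        assert r.symmetry == 2

    def test_mapping_rule_symmetry_equals_automorphisms(self):
        # whole-complex deletion is preserved by every automorphism
        r = Rule("map", [parse_pattern("L(r,r,r)")],
                 [SiteGraph([Molecule("pop_L", [], is_population=True)])],
                 1e4, is_population_map=True)
        assert r.symmetry == 6

    def test_symmetric_dimerization_flux_matches_cme(self):
        # s must make the enumerated network's equilibrium match the exact
        # CME on a 4-particle A(a)+A(a)<->A.A system
        text = """
        begin model
        begin parameters
          kf 0.1
          kr 1.0
        end parameters
        begin molecule types
          A(a)
        end molecule types
        begin seed species
          A(a) 4
        end seed species
        begin observables
          Molecules Dimers A(a!1).A(a!1)
        end observables
        begin reaction rules
          1: A(a) + A(a) <-> A(a!1).A(a!1)  kf, kr
        end reaction rules
        end model
        """
        m = read_model(text)
        net = generate_network(m)
        # CME over number of dimers d in {0,1,2}; monomers n=4-2d
        # forward rate kf/2*n*(n-1), backward kr*d
        kf, kr = 0.1, 1.0
        Q = np.zeros((3, 3))
        for d in range(3):
            n = 4 - 2 * d
            if d < 2:
                Q[d, d + 1] = kf / 2 * n * (n - 1)
            if d > 0:
                Q[d, d - 1] = kr * d
            Q[d, d] = -Q[d].sum()
        from scipy.linalg import eig
        w, vl = eig(Q.T)
        pi = np.real(vl[:, np.argmin(abs(w))])
        pi /= pi.sum()
        mean_d = float(pi @ np.arange(3))
        tr = simulate_ssa(net, 4000.0, seed=5, n_steps=8000)
        observed = tr.observable("Dimers")[2000:].mean() / 2.0
        # Dimers observable counts embeddings (2 per dimer)
        se = 3 * pi.std() / np.sqrt(50)  # loose Monte-Carlo band
        assert observed == pytest.approx(mean_d, abs=0.12)


class TestSpeciesEqualsPattern:
    def test_examples(self, receptor_model):
        m = receptor_model
        L = parse_pattern("L(r)")
        assert species_equals_pattern(m, L, parse_pattern("L(r)"))
        assert not species_equals_pattern(
            m, parse_pattern("L(r!+)"), parse_pattern("L(r)"))
        assert not species_equals_pattern(
            m, parse_pattern("A(r)"), parse_pattern("A(r,s~U,b)"))
        assert species_equals_pattern(
            m, parse_pattern("A(b,r,s~P)"), parse_pattern("A(r,s~P,b)"))

    def test_agrees_with_canonical_equality(self, receptor_model, rng):
        m = receptor_model
        species = [g for g, _ in m.seeds]
        for a in species:
            for b in species:
                assert species_equals_pattern(m, a, b) == \
                    (canonical_label(a) == canonical_label(b))
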