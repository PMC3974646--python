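"""The population-adapted network-free engine."""

import numpy as np
import pytest

from hppsim import (read_model, transform_model, simulate, SystemState,
                    generate_network, simulate_ssa, parse_pattern,
                    generate_random_model, ParticleCapError)
from hppsim.engine import reject_symmetric_null, EngineError
from hppsim.model import PopulationMap

POP_PAIR = """
begin model
begin molecule types
  A(a)
  pop_A() population
  pop_B() population
end molecule types
begin seed species
  pop_A() {pa}
  pop_B() {pb}
end seed species
begin observables
  Molecules Dimer A(a!1).A(a!1)
  Molecules PoolA pop_A()
end observables
begin reaction rules
  1: pop_A() + pop_B() -> A(a!1).A(a!1)  2.0
end reaction rules
end model
"""

SYM_POP = """
begin model
begin molecule types
  A(a)
  pop_A() population
end molecule types
begin seed species
  pop_A() {p}
end seed species
begin observables
  Molecules Dimer A(a!1).A(a!1)
end observables
begin reaction rules
  1: pop_A() + pop_A() -> A(a!1).A(a!1)  {k}
end reaction rules
end model
"""


class TestPropensity:
    def test_pure_population_rule(self):
        m = read_model(POP_PAIR.format(pa=10, pb=4))
        st = SystemState(m)
        a = st.propensities()
        assert a.tolist() == [2.0 * 10 * 4]

    def test_no_population_limit_equals_network_free(self, receptor_model):
        # all p_k = 1: the propensity is (k/s) * prod of total match counts
        st = SystemState(receptor_model)
        a = st.propensities()
        assert a.tolist() == st.propensities_brute().tolist()
        # spot-check ligand binding: kpL * 10000 * 300
        rule_i = next(i for i, r in enumerate(st._rules) if r.name == "1f")
        assert a[rule_i] == pytest.approx(1e-4 * 10000 * 300)

    def test_symmetric_population_propensity_uses_s2(self):
        m = read_model(SYM_POP.format(p=10, k=2.0))
        st = SystemState(m)
        assert st._rules[0].symmetry == 2
        assert st.propensities().tolist() == [2.0 / 2 * 10 * 10]

    def test_particle_expansion_oracle_on_hybrid_states(self):
        # Eq.-1 propensities must equal an independent brute-force sum over
        # explicit reactant tuples, with every counter expanded into that
        # many identical copies (M = 1 per copy for a population pattern,
        # 0 for structured patterns, which never match counters)
        checked = 0
        for seed in range(8):
            text = generate_random_model(seed)
            m = read_model(text)
            if not m.population_maps:
                continue
            hyb = transform_model(m)
            st = SystemState(hyb)
            a = st.propensities()
            b = _oracle_propensities(hyb)
            assert np.allclose(a, b), text
            checked += 1
        assert checked >= 3

    def test_incremental_bookkeeping_stays_in_sync(self, receptor_model):
        # after thousands of firings the incremental totals must equal a
        # from-scratch recomputation
        hyb = transform_model(receptor_model)
        for model in (receptor_model, hyb):
            rng = np.random.default_rng(9)
            st = SystemState(model)
            fired = 0
            for _ in range(1500):
                a = st.propensities()
                tot = a.sum()
                if tot <= 0:
                    break
                u = rng.random() * tot
                ri = int(np.searchsorted(np.cumsum(a), u, side="right"))
                if st.fire(min(ri, len(a) - 1), rng) == "fired":
                    fired += 1
            assert fired > 100
            assert np.allclose(st.propensities(), st.propensities_brute())
            assert all(v >= 0 for v in st.counters.values())


def _oracle_propensities(hyb):
    """Independent Eq.-1 evaluation from the initial state description:
    per-slot totals via SiteGraph matching over explicit particle lists
    (counters expanded to identical copies), never via the engine."""
    from hppsim import find_matches
    particles = []
    for g, n in hyb.seeds:
        particles.extend([g] * int(round(n)))
    pools = {nm: int(round(n)) for nm, n in hyb.pop_seeds}
    out = []
    for r in hyb.rules:
        if r.is_population_map:
            a = r.rate / r.symmetry * sum(
                len(find_matches(r.reactants[0], g)) for g in particles)
            out.append(a)
            continue
        a = r.rate / r.symmetry
        for pat in r.reactants:
            if pat.molecules[0].is_population:
                # expanded copies: one match per copy
                a *= pools.get(pat.molecules[0].name, 0)
            else:
                a *= sum(len(find_matches(pat, g)) for g in particles)
        out.append(a)
    return np.array(out)


class TestFiring:
    def test_poisson_firing_count(self):
        # a rule that changes nothing has constant propensity k*n; firings
        # over [0, t] are Poisson(k*n*t)
        text = ("begin molecule types\nA(x)\nend molecule types\n"
                "begin seed species\nA(x) 10\nend seed species\n"
                "begin reaction rules\n1: A(x) -> A(x)  1.0\n"
                "end reaction rules\n")
        m = read_model(text)
        tr = simulate(m, 10.0, seed=12, n_steps=5)
        lam = 100.0
        assert abs(tr.total_firings - lam) < 3 * np.sqrt(lam)

    def test_symmetric_population_rates(self):
        # accepted event rate for pop_A()+pop_A() with s=2 equals the
        # enumerated dimerization reaction's propensity k*p*(p-1)/2: the
        # time to the first firing is exponential at exactly that rate
        k = 0.01
        n_rep = 300
        for p, seed in ((2, 1), (5, 2), (20, 3)):
            m = read_model(SYM_POP.format(p=p, k=k))
            rate = k / 2 * p * (p - 1)
            waits = []
            for i in range(n_rep):
                rng = np.random.default_rng(seed * 10_000 + i)
                st = SystemState(m)
                t = 0.0
                while True:
                    a = st.propensities().sum()
                    t += rng.exponential(1.0 / a)
                    if st.fire(0, rng) == "fired":
                        break
                waits.append(t)
            est = 1.0 / np.mean(waits)
            se = rate / np.sqrt(n_rep)
            assert abs(est - rate) < 3.5 * se, (p, est, rate)

    def test_p_equal_one_never_fires(self):
        m = read_model(SYM_POP.format(p=1, k=5.0))
        tr = simulate(m, 50.0, seed=4, n_steps=5)
        assert tr.total_firings == 0
        assert tr.null_events > 0  # clock advances, events rejected

    def test_rejection_probability_direct(self):
        rng = np.random.default_rng(0)
        assert all(reject_symmetric_null(1, rng) for _ in range(100))
        nulls = sum(reject_symmetric_null(2, rng) for _ in range(100_000))
        assert abs(nulls / 100_000 - 0.5) < 3 * 0.5 / np.sqrt(100_000)
        with pytest.raises(EngineError):
            reject_symmetric_null(0, rng)

    def test_mapping_rule_lumps_particle(self):
        text = """
begin molecule types
  E(r)
  pop_E() population
end molecule types
begin seed species
  E(r) 5
end seed species
begin observables
  Molecules Pool pop_E()
  Molecules Free E(r)
end observables
begin reaction rules
  1: E(r) -> pop_E()  100.0
end reaction rules
"""
        m = read_model(text)
        m.rules[0].is_population_map = True
        tr = simulate(m, 1.0, seed=6, n_steps=10)
        # every particle deleted, every deletion increments the counter;
        # the structured pattern no longer matches anything
        assert tr.values[-1].tolist() == [5.0, 0.0]
        assert tr.mapping_firings == 5
        assert tr.firings_excluding_mapping == 0


class TestObservables:
    def test_counter_observable(self):
        m = read_model(POP_PAIR.format(pa=7, pb=0))
        tr = simulate(m, 1.0, seed=1, n_steps=2)
        assert tr.observable("PoolA")[-1] == 7.0

    def test_per_embedding_counting(self):
        text = ("begin molecule types\nL(r,r,r)\nR(l,l)\nend molecule types\n"
                "begin seed species\nL(r!1,r!2,r).R(l!1,l!2) 1\n"
                "end seed species\n"
                "begin observables\nMolecules Bound L(r!+)\n"
                "Species Complexes L(r!?)\nend observables\n")
        m = read_model(text)
        tr = simulate(m, 1.0, seed=1, n_steps=2)
        assert tr.observable("Bound")[-1] == 2.0
        assert tr.observable("Complexes")[-1] == 1.0


class TestSimulate:
    def test_zero_propensity_flat(self):
        m = read_model("begin molecule types\nA(x)\nend molecule types\n"
                       "begin seed species\nA(x) 3\nend seed species\n"
                       "begin observables\nMolecules N A(x)\n"
                       "end observables\n")
        tr = simulate(m, 10.0, seed=1, n_steps=20)
        assert tr.total_firings == 0
        assert (tr.observable("N") == 3.0).all()

    def test_determinism_bit_identical(self, receptor_model):
        hyb = transform_model(receptor_model)
        a = simulate(hyb, 3.0, seed=123, n_steps=30)
        b = simulate(hyb, 3.0, seed=123, n_steps=30)
        assert a.to_gdat() == b.to_gdat()
        assert a.total_firings == b.total_firings
        assert a.firings_by_rule == b.firings_by_rule

    def test_particle_cap(self):
        m = read_model("begin molecule types\nA(x)\nend molecule types\n"
                       "begin seed species\nA(x) 100\nend seed species\n")
        with pytest.raises(ParticleCapError):
            simulate(m, 1.0, seed=1, cap=10)

    def test_all_lumped_matches_cme(self):
        from test_network import AB_MODEL, cme_mean_ab
        m = read_model(AB_MODEL)
        maps = [PopulationMap(parse_pattern("A(b)"), "pop_A", 1e4),
                PopulationMap(parse_pattern("B(a)"), "pop_B", 1e4),
                PopulationMap(parse_pattern("A(b!1).B(a!1)"), "pop_AB", 1e4)]
        from hppsim.model import MoleculeType
        for nm in ("pop_A", "pop_B", "pop_AB"):
            m.molecule_types[nm] = MoleculeType(nm, [], is_population=True)
        hyb = transform_model(m, pop_maps=maps)
        tr = simulate(hyb, 3000.0, seed=7, n_steps=6000)
        mean = tr.observable("AB")[1500:].mean()
        assert mean == pytest.approx(cme_mean_ab(), abs=0.12)


class TestPatternSharing:
    def test_isomorphic_patterns_with_different_component_order(self):
        # two rules whose patterns are isomorphic but list components in a
        # different order must not share transformation loci; regression
        # test for head-to-head (p-p) bond corruption in polymer models
        text = """
begin molecule types
  A(b,p)
end molecule types
begin seed species
  A(b,p) 30
end seed species
begin observables
  Molecules BadFree A(b)
end observables
begin reaction rules
  1: A(b) + A(p,b) -> A(b!1).A(p!1,b)  0.05
  2: A(p) + A(b,p) -> A(p!1).A(b!1,p)  0.05
end reaction rules
"""
        m = read_model(text)
        tr = simulate(m, 5.0, seed=3, n_steps=5, cap=1000)
        st = SystemState(m)
        rng = np.random.default_rng(1)
        for _ in range(60):
            a = st.propensities()
            if a.sum() <= 0:
                break
            u = rng.random() * a.sum()
            ri = int(min(np.searchsorted(np.cumsum(a), u), len(a) - 1))
            st.fire(ri, rng)
        for cset in st.complexes.values():
            for mol in cset:
                for ci, b in enumerate(mol.bonds):
                    if b is not None:
                        other, oci = b
                        assert {mol.cnames[ci], other.cnames[oci]} == \
                            {"b", "p"}, "malformed bond"
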