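"""Fixture building, random models, and the statistical machinery."""

import itertools

import numpy as np
import pytest

from hppsim import (read_model, build_fixture, FixtureSpec, transform_model,
                    simulate, generate_network, simulate_ssa,
                    generate_random_model, compare_firings,
                    compare_distributions, EquivalenceReport,
                    rank_species_by_mean_population, lump_by_threshold,
                    canonical_label)
from hppsim.engine import SystemState
from hppsim.model import ModelError


class TestBuildFixture:
    def test_tlbr_structure(self):
        m = build_fixture(FixtureSpec("tlbr"))
        assert len(m.rules) == 4
        assert len(m.population_maps) == 2

    def test_identity_scaling(self):
        m1 = build_fixture(FixtureSpec("tlbr", f=1.0))
        m2 = build_fixture(FixtureSpec("tlbr"))
        assert [n for _, n in m1.seeds] == [n for _, n in m2.seeds]
        assert [r.rate for r in m1.rules] == [r.rate for r in m2.rules]

    def test_volume_scaling_preserves_initial_propensity_scale(self):
        # at fixed concentration the per-volume propensity is invariant:
        # a(f) = f * a(1) for every rule at t = 0
        m1 = build_fixture(FixtureSpec("receptor_activation", f=1.0))
        f = 0.01
        m2 = build_fixture(FixtureSpec("receptor_activation", f=f))
        a1 = SystemState(m1).propensities()
        a2 = SystemState(m2).propensities()
        nz = a1 > 0
        assert np.allclose(a2[nz] / a1[nz], f, rtol=0.02)

    def test_unknown_fixture_and_bad_fraction(self):
        with pytest.raises(ModelError):
            FixtureSpec("nope")
        with pytest.raises(ModelError):
            FixtureSpec("tlbr", f=0.0)

    def test_fceri_population_sets(self):
        m1 = build_fixture(FixtureSpec("fceri_gamma2", pop_set="default"))
        m6 = build_fixture(FixtureSpec("fceri_gamma2", pop_set="6"))
        assert len(m1.population_maps) == 1
        assert len(m6.population_maps) == 6

    def test_k_lump_override(self):
        m = build_fixture(FixtureSpec("tlbr", k_lump=123.0))
        assert all(pm.k_lump == 123.0 for pm in m.population_maps)


class TestRandomModels:
    def test_reproducible(self):
        assert generate_random_model(5) == generate_random_model(5)

    @pytest.mark.parametrize("seed", range(8))
    def test_valid_finite_and_round_trips(self, seed):
        from hppsim import write_model
        text = generate_random_model(seed)
        m = read_model(text)
        net = generate_network(m, max_species=5000)  # finite by construction
        assert net.n_species >= len(m.seeds)
        m2 = read_model(write_model(m))
        assert len(m2.rules) == len(m.rules)

    def test_cross_engine_firing_equivalence(self):
        # SSA vs NF vs HPP on random finite models (reduced-scale protocol)
        n_runs, t_end = 12, 4.0
        for seed in (1, 2, 4):
            m = read_model(generate_random_model(seed))
            hyb = transform_model(m)
            net = generate_network(m, max_species=5000)
            samples = {"ssa": [], "nf": [], "hpp": []}
            for i in range(n_runs):
                samples["ssa"].append(
                    simulate_ssa(net, t_end, seed=i, n_steps=2).total_firings)
                samples["nf"].append(
                    simulate(m, t_end, seed=300 + i, n_steps=2).total_firings)
                samples["hpp"].append(
                    simulate(hyb, t_end, seed=600 + i,
                             n_steps=2).firings_excluding_mapping)
            rep = EquivalenceReport(["ssa", "nf", "hpp"], samples)
            assert rep.passes(alpha=0.01), (seed, rep.summary())


class TestCompareFirings:
    def test_complete_separation_matches_enumeration(self):
        a, b = [1, 2, 3], [10, 11, 12]
        p = compare_firings(a, b)
        # exhaustive two-sided enumeration over all C(6,3)=20 arrangements
        pooled = a + b
        stats = []
        for comb in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in comb]
            gb = [pooled[j] for j in range(6) if j not in comb]
            stats.append(sum(1 for x in ga for y in gb if x > y))
        observed = 0  # every a below every b
        extreme = sum(1 for u in stats
                      if min(u, 9 - u) <= min(observed, 9 - observed))
        assert p == pytest.approx(extreme / len(stats))

    def test_small_sample_matches_exact_enumeration(self):
        a, b = [3, 5, 9], [4, 8, 12]
        p = compare_firings(a, b)
        pooled = a + b
        u_obs = sum(1 for x in a for y in b if x > y)
        stats = []
        for comb in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in comb]
            gb = [pooled[j] for j in range(6) if j not in comb]
            stats.append(sum(1 for x in ga for y in gb if x > y))
        # two-sided: arrangements at least as extreme (U distance from mean)
        mu = 4.5
        extreme = sum(1 for u in stats if abs(u - mu) >= abs(u_obs - mu))
        assert p == pytest.approx(extreme / len(stats))

    def test_calibration_under_the_null(self):
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 800
        for _ in range(n_rep):
            a = rng.normal(0, 1, 10)
            b = rng.normal(0, 1, 10)
            if compare_firings(a, b) < 0.05:
                rejections += 1
        rate = rejections / n_rep
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            compare_firings([], [1.0])


class TestCompareDistributions:
    def test_identical_histograms_give_zero(self):
        a = np.repeat([1.0, 2.0, 3.0], 40)
        stat, p, dof = compare_distributions(a, a.copy(), n_bins=3)
        assert stat == 0.0 and p == 1.0

    def test_two_bin_closed_form(self):
        # 2 bins; group A: (30, 10), group B: (20, 20); chi2 computable by
        # hand from the pooled expectations
        a = np.array([0.0] * 30 + [1.0] * 10)
        b = np.array([0.0] * 20 + [1.0] * 20)
        stat, p, dof = compare_distributions(a, b, n_bins=2,
                                             min_expected=1.0)
        oa, ob = np.array([30, 10]), np.array([20, 20])
        ea = (oa + ob) * 0.5
        expected = (((oa - ea) ** 2) / ea).sum() + (((ob - ea) ** 2) / ea).sum()
        assert stat == pytest.approx(expected)
        assert dof == 1

    def test_degenerate_binning_errors(self):
        with pytest.raises(ValueError):
            compare_distributions([2.0] * 30, [2.0] * 30)

    def test_same_distribution_not_rejected(self):
        rng = np.random.default_rng(3)
        a = rng.poisson(30, 400).astype(float)
        b = rng.poisson(30, 400).astype(float)
        stat, p, dof = compare_distributions(a, b)
        assert p > 0.05


TOY = """
begin model
begin molecule types
  A(b)
  B(a)
  pop_A() population
  pop_B() population
  pop_AB() population
end molecule types
begin seed species
  A(b) 40
  B(a) 25
end seed species
begin observables
  Molecules AB A(b!1).B(a!1)
end observables
begin reaction rules
  1: A(b) + B(a) <-> A(b!1).B(a!1)  0.01, 0.5
end reaction rules
begin population maps
  A(b) -> pop_A()  1e4
  B(a) -> pop_B()  1e4
  A(b!1).B(a!1) -> pop_AB()  1e4
end population maps
end model
"""


class TestSpeciesRanking:
    def test_threshold_above_everything_is_empty(self):
        m = read_model(TOY)
        table = rank_species_by_mean_population(m, 10.0, 1.0, seed=1)
        assert lump_by_threshold(m, table, threshold=1e9) == []

    def test_threshold_monotonicity(self):
        m = read_model(TOY)
        table = rank_species_by_mean_population(m, 10.0, 1.0, seed=1)
        sets = []
        for thr in (20.0, 5.0, 0.0):
            maps = lump_by_threshold(m, table, thr)
            sets.append({canonical_label(pm.structured) for pm in maps})
        assert sets[0] <= sets[1] <= sets[2]

    def test_threshold_zero_lumps_everything_and_matches_ssa(self):
        m = read_model(TOY)
        table = rank_species_by_mean_population(m, 20.0, 0.5, seed=2)
        maps = lump_by_threshold(m, table, threshold=0.0)
        assert len(maps) == len(table)  # every species lumped
        hyb = transform_model(m, pop_maps=maps)
        net = generate_network(m)
        hpp = [simulate(hyb, 8.0, seed=10 + i,
                        n_steps=2).firings_excluding_mapping
               for i in range(12)]
        ssa = [simulate_ssa(net, 8.0, seed=400 + i, n_steps=2).total_firings
               for i in range(12)]
        assert compare_firings(hpp, ssa) > 0.01

    def test_recovers_receptor_activation_population_set(self,
                                                         receptor_model):
        # a mid-range threshold on the pre-simulation table reproduces the
        # eight hand-picked receptor-free population species
        m = build_fixture(FixtureSpec("receptor_activation", f=0.1))
        table = rank_species_by_mean_population(m, 30.0, 1.0, seed=3)
        maps = lump_by_threshold(m, table, threshold=5.0)
        got = {canonical_label(pm.structured) for pm in maps}
        expected = {canonical_label(pm.structured)
                    for pm in receptor_model.population_maps}
        assert got == expected
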