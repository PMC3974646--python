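"""Statistical equivalence machinery and population-species selection.

Exact-stochastic engines (SSA, network-free, hybrid) must produce
statistically identical reaction-firing counts; ``compare_firings`` applies
the two-sided Mann-Whitney U test to per-run firing samples
(population-mapping firings are excluded upstream).  Equilibrium
distributions (e.g. receptor-cluster counts, polymer lengths) are compared
with a two-sample chi-squared test on a common 20-bin histogram.

``rank_species_by_mean_population`` implements the systematic
population-species selection: a single network-free pre-simulation is
sampled at periodic intervals, every complex is canonically labeled, and
per-species time-averaged populations are returned; ``lump_by_threshold``
turns every species above a threshold into a population map.
"""

from __future__ import annotations

import json

import numpy as np
from scipy import stats

from .sitegraph import canonical_label
from .bngl import parse_pattern
from .model import ModelDocument, ModelError, PopulationMap
from .engine import simulate


def compare_firings(samples_a, samples_b):
    """Two-sided Mann-Whitney U p-value for two firing-count samples.

    Uses exact enumeration for small tie-free samples and the normal
    approximation with tie correction otherwise (scipy's "auto" policy)."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.pvalue)


def compare_distributions(samples_a, samples_b, n_bins: int = 20,
                          min_expected: float = 5.0):
    """Two-sample chi-squared comparison on a common binning.

    Samples are pooled to define ``n_bins`` equal-width bins; adjacent bins
    are merged until every expected count reaches ``min_expected``.
    Returns ``(statistic, p_value, dof)``."""
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        raise ValueError("degenerate binning: all samples identical")
    edges = np.linspace(lo, hi, n_bins + 1)
    oa, _ = np.histogram(a, bins=edges)
    ob, _ = np.histogram(b, bins=edges)

    # merge adjacent bins until expected counts are adequate
    na, nb = a.size, b.size
    oa_m, ob_m = [], []
    ca = cb = 0
    for i in range(len(oa)):
        ca += oa[i]
        cb += ob[i]
        tot = ca + cb
        ea = tot * na / (na + nb)
        eb = tot * nb / (na + nb)
        if ea >= min_expected and eb >= min_expected:
            oa_m.append(ca)
            ob_m.append(cb)
            ca = cb = 0
    if ca or cb:
        if oa_m:
            oa_m[-1] += ca
            ob_m[-1] += cb
        else:
            raise ValueError("degenerate binning: too few samples to bin")
    oa_m = np.asarray(oa_m, dtype=float)
    ob_m = np.asarray(ob_m, dtype=float)
    if len(oa_m) < 2:
        raise ValueError("degenerate binning: fewer than two usable bins")
    ea = (oa_m + ob_m) * na / (na + nb)
    eb = (oa_m + ob_m) * nb / (na + nb)
    statistic = float((((oa_m - ea) ** 2) / ea).sum()
                      + (((ob_m - eb) ** 2) / eb).sum())
    dof = len(oa_m) - 1
    p = float(stats.chi2.sf(statistic, dof))
    return statistic, p, dof


class EquivalenceReport:
    """Firing samples per engine plus the pairwise test results."""

    def __init__(self, engines, samples):
        self.engines = list(engines)
        self.samples = {k: list(map(float, v)) for k, v in samples.items()}
        self.u_pvalues = {}
        for i, a in enumerate(self.engines):
            for b in self.engines[i + 1:]:
                self.u_pvalues[f"{a}-vs-{b}"] = compare_firings(
                    self.samples[a], self.samples[b])
        self.chi2 = {}

    def add_distribution_test(self, name, samples_a, samples_b, n_bins=20):
        stat, p, dof = compare_distributions(samples_a, samples_b, n_bins)
        self.chi2[name] = {"statistic": stat, "p": p, "dof": dof}
        return p

    def summary(self):
        out = {
            "engines": self.engines,
            "n_runs": {k: len(v) for k, v in self.samples.items()},
            "firing_means": {k: float(np.mean(v))
                             for k, v in self.samples.items()},
            "mann_whitney_p": self.u_pvalues,
        }
        if self.chi2:
            out["chi squared"] = self.chi2
        return out

    def to_json(self):
        return json.dumps(self.summary(), indent=2, sort_keys=True)

    def passes(self, alpha: float = 0.05) -> bool:
        ok = all(p >= alpha for p in self.u_pvalues.values())
        ok = ok and all(d["p"] >= alpha for d in self.chi2.values())
        return ok


# ---------------------------------------------------------------------------
# Systematic population-species selection
# ---------------------------------------------------------------------------

def rank_species_by_mean_population(model: ModelDocument, t_end: float,
                                    sample_interval: float, seed: int,
                                    cap: int = 5_000_000):
    """Time-averaged per-species populations from one network-free run.

    At each sampling time the full set of complexes is collected, each
    complex canonically labeled, and the instances per label counted;
    averages are over all samples.  Returns a list of (label, mean count)
    sorted by decreasing mean."""
    times = np.arange(0.0, t_end + 0.5 * sample_interval, sample_interval)
    totals: dict = {}
    n_samples = [0]

    def snap(t, state):
        n_samples[0] += 1
        seen: dict = {}
        for g in state.complex_graphs():
            lab = canonical_label(g)
            seen[lab] = seen.get(lab, 0) + 1
        for lab, c in seen.items():
            totals[lab] = totals.get(lab, 0) + c

    simulate(model, t_end, seed=seed, n_steps=1, cap=cap,
             snapshot_times=times, snapshot_fn=snap)
    if n_samples[0] == 0:
        raise ValueError("no samples collected")
    table = [(lab, tot / n_samples[0]) for lab, tot in totals.items()]
    table.sort(key=lambda kv: (-kv[1], kv[0]))
    return table


def lump_by_threshold(model: ModelDocument, table, threshold: float,
                      k_lump: float = 1e4, prefix: str = "pop_"):
    """Population maps for every species whose average population exceeds
    the threshold; species that cannot serve as population species are
    skipped with a warning entry."""
    import warnings
    maps = []
    for i, (label, mean) in enumerate(table):
        if mean <= threshold:
            continue
        graph = parse_pattern(label)
        try:
            model.check_species(graph, "lump candidate")
        except ModelError as e:
            warnings.warn(f"skipping lump candidate {label}: {e}")
            continue
        maps.append(PopulationMap(graph, f"{prefix}S{i}", k_lump))
    return maps
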