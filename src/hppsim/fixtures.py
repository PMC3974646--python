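"""Packaged example models, volume scaling, and a random-model generator.

The example models (receptor activation, TLBR, actin, FcεRI gamma2,
extended EGFR) ship as BNGL-subset text files under ``hppsim/data``.
``build_fixture`` loads one, applies the volume-fraction transform and the
requested population set, and returns a ready-to-run model.

Volume fraction ``f`` scales particle numbers at fixed concentration:
seed counts are multiplied by ``f`` (rounded to nearest integer) and
bimolecular rate constants by ``1/f``; unimolecular rates, including the
lumping rate constant, are untouched.
"""

from __future__ import annotations

import importlib.resources as ir

import numpy as np

from .bngl import read_model, parse_pattern
from .model import ModelDocument, ModelError, PopulationMap

FIXTURE_IDS = ("receptor_activation", "tlbr", "actin", "fceri_gamma2",
               "egfr")

_FILES = {
    "receptor_activation": "receptor_activation.bngl",
    "tlbr": "tlbr.bngl",
    "actin": "actin_simple.bngl",
    "fceri_gamma2": "fceri_gamma2.bngl",
    "egfr": "egfr_extended.bngl",
}

# FcεRI population-set variants: "1" lumps free ligand only, "6" also lumps
# cytosolic Lyn and the four phosphoforms of cytosolic Syk.
_FCERI_EXTRA_POPS = [
    ("Lyn(u,sh2)", "pop_Lyn"),
    ("Syk(tsh2,l~Y,a~Y)", "pop_Syk_YY"),
    ("Syk(tsh2,l~pY,a~Y)", "pop_Syk_pY"),
    ("Syk(tsh2,l~Y,a~pY)", "pop_Syk_Yp"),
    ("Syk(tsh2,l~pY,a~pY)", "pop_Syk_pp"),
]


class FixtureSpec:
    """Which model, at what scale, with which population set.

    Parameters mirror the performance-test protocol: ``f`` is the
    fractional cell volume (0 < f <= 1), ``k_lump`` overrides the lumping
    rate constant, ``pop_set`` selects among packaged population sets
    (only FcεRI has two: "1" and "6"), ``t_end`` overrides the packaged
    simulation horizon."""

    def __init__(self, model_id, f=1.0, k_lump=None, pop_set="default",
                 t_end=None):
        if model_id not in FIXTURE_IDS:
            raise ModelError(f"unknown fixture id {model_id!r}")
        if not (0.0 < f <= 1.0):
            raise ModelError("volume fraction must be in (0, 1]")
        if t_end is not None and t_end <= 0:
            raise ModelError("t_end must be positive")
        self.model_id = model_id
        self.f = f
        self.k_lump = k_lump
        self.pop_set = pop_set
        self.t_end = t_end


def fixture_text(model_id: str) -> str:
    return (ir.files("hppsim") / f"data/{_FILES[model_id]}").read_text()


def load_fixture_model(model_id: str) -> ModelDocument:
    return read_model(fixture_text(model_id))


def scale_volume(model: ModelDocument, f: float) -> ModelDocument:
    """In-place volume-fraction transform (returns the model)."""
    if f == 1.0:
        return model
    model.seeds = [(g, float(round(n * f))) for (g, n) in model.seeds]
    model.pop_seeds = [(nm, float(round(n * f))) for (nm, n) in model.pop_seeds]
    for r in model.rules:
        if len(r.reactants) == 2:
            r.rate /= f
    model.config["f"] = f
    return model


def scale_volume_network(network, f: float):
    """Volume-fraction transform applied to an already generated network
    (counts scaled by f, bimolecular rate constants by 1/f); mirrors
    :func:`scale_volume` so a fixed-point network need only be generated
    once per fixture."""
    import copy
    out = copy.deepcopy(network)
    out.initial_counts = [float(round(c * f)) for c in out.initial_counts]
    for r in out.reactions:
        if len(r.reactants) == 2:
            r.rate /= f
    return out


def build_fixture(spec: FixtureSpec) -> ModelDocument:
    """Load, scale and configure a packaged example model."""
    model = load_fixture_model(spec.model_id)
    if spec.model_id == "fceri_gamma2" and spec.pop_set in ("6", 6):
        k = model.population_maps[0].k_lump
        for pat, name in _FCERI_EXTRA_POPS:
            model.population_maps.append(
                PopulationMap(parse_pattern(pat), name, k))
    if spec.k_lump is not None:
        model.population_maps = [
            PopulationMap(pm.structured, pm.unstructured_name, spec.k_lump)
            for pm in model.population_maps]
    scale_volume(model, spec.f)
    if spec.t_end is not None:
        model.config["t_end"] = float(spec.t_end)
    return model


# ---------------------------------------------------------------------------
# Random finite models for property testing
# ---------------------------------------------------------------------------

def generate_random_model(seed: int, max_types: int = 4,
                          max_rules: int = 10) -> str:
    """Emit a random, syntactically valid, finite-network model (BNGL text).

    Finiteness is guaranteed by a tree-structured binding topology: each
    molecule type has one "uplink" site binding a designated site of a
    strictly earlier type, so every complex is a bounded tree.  A random
    subset of the free (seed) species is declared lumpable via population
    maps.  Identical seeds give identical text."""
    rng = np.random.default_rng(seed)
    n_types = int(rng.integers(2, max_types + 1))
    names = [f"M{i}" for i in range(n_types)]

    comps = {}          # type -> list of (comp, states or None)
    uplink = {}         # type -> (comp, parent type, parent comp)
    downlinks = {i: [] for i in range(n_types)}
    for i in range(n_types):
        clist = [("u", None)] if i > 0 else []
        # optional state site
        if rng.random() < 0.7:
            clist.append(("s", ("a", "b")))
        comps[i] = clist
    # each type i>0 binds a fresh downlink site on a random earlier type
    for i in range(1, n_types):
        parent = int(rng.integers(0, i))
        site = f"d{len(downlinks[parent])}"
        comps[parent].append((site, None))
        downlinks[parent].append((site, i))
        uplink[i] = (site, parent)

    lines = ["begin model", "begin parameters"]
    params = {}

    def param(base, lo, hi):
        name = f"{base}{len(params)}"
        params[name] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
        lines.append(f"  {name} {params[name]:.4g}")
        return name

    rules = []
    for i in range(1, n_types):
        site, parent = uplink[i]
        kon = param("kon", 1e-3, 1e-2)
        koff = param("koff", 0.05, 1.0)
        rules.append(
            f"{names[parent]}({site}) + {names[i]}(u) <-> "
            f"{names[parent]}({site}!1).{names[i]}(u!1)  {kon}, {koff}")
    for i in range(n_types):
        if any(c == "s" for c, _ in comps[i]):
            k1 = param("kf", 0.05, 0.5)
            k2 = param("kb", 0.05, 0.5)
            if i > 0 and rng.random() < 0.5:
                # state flip conditioned on being bound
                rules.append(f"{names[i]}(u!+,s~a) -> {names[i]}(u!+,s~b)  {k1}")
            else:
                rules.append(f"{names[i]}(s~a) -> {names[i]}(s~b)  {k1}")
            rules.append(f"{names[i]}(s~b) -> {names[i]}(s~a)  {k2}")
    rules = rules[:max_rules]
    counts = {i: int(rng.integers(20, 80)) for i in range(n_types)}
    lump = [i for i in range(n_types) if rng.random() < 0.6]

    lines.append("end parameters")
    lines.append("begin molecule types")
    for i in range(n_types):
        cl = []
        for c, states in comps[i]:
            cl.append(c + ("".join("~" + s for s in states) if states else ""))
        lines.append(f"  {names[i]}({','.join(cl)})")
    for i in lump:
        lines.append(f"  pop_{names[i]}() population")
    lines.append("end molecule types")
    lines.append("begin seed species")

    def free_species(i):
        cl = []
        for c, states in comps[i]:
            cl.append(c + ("~a" if states else ""))
        return f"{names[i]}({','.join(cl)})"

    for i in range(n_types):
        lines.append(f"  {free_species(i)} {counts[i]}")
    lines.append("end seed species")
    lines.append("begin observables")
    lines.append(f"  Molecules bound0 {names[0]}(d0!+)"
                 if downlinks[0] else f"  Molecules n0 {names[0]}()")
    lines.append("end observables")
    lines.append("begin reaction rules")
    for j, r in enumerate(rules, 1):
        lines.append(f"  {j}: {r}")
    lines.append("end reaction rules")
    if lump:
        lines.append("begin population maps")
        for i in lump:
            lines.append(f"  {free_species(i)} -> pop_{names[i]}()  1e4")
        lines.append("end population maps")
    lines.append("end model")
    return "\n".join(lines) + "\n"
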