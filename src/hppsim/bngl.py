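"""Reader/writer for the BNGL-subset dialect used by this package.

Supported blocks: ``parameters``, ``molecule types``, ``seed species``,
``observables``, ``reaction rules``, ``population maps``, ``config`` — each
wrapped in ``begin <name>`` / ``end <name>`` lines, optionally inside a
``begin model`` / ``end model`` pair.  Comments start with ``#``.

Extensions over plain BNGL: the ``population`` keyword on a molecule-type
declaration marks an unstructured counter species, and the ``population
maps`` block holds lines of the form::

    StructuredSpecies -> pop_Name()  k_lump

Parameter expressions support ``+ - * / ^``, parentheses, scientific
notation and references to previously defined parameters.

Not supported (out of scope): compartments, functions, energy patterns,
molecule hierarchies.
"""

from __future__ import annotations

import re
from typing import Optional

from .sitegraph import SiteGraph, Molecule, Component
from .model import (ModelDocument, MoleculeType, Rule, PopulationMap,
                    Observable, ModelError)


class ParseError(ModelError):
    def __init__(self, msg, line_no=None, line=None):
        loc = f" (line {line_no}: {line!r})" if line_no else ""
        super().__init__(msg + loc)
        self.line_no = line_no


_NAME = r"[A-Za-z_][A-Za-z0-9_]*"
_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>" + _NAME + r")"
    r"|(?P<arrow><->|->)"
    r"|(?P<sym>[().,~!+?:*/^$-]))")


def _tokenize(text):
    out = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"cannot tokenize near {text[pos:pos+12]!r}")
        pos = m.end()
        if m.lastgroup == "num":
            out.append(("num", m.group("num")))
        elif m.lastgroup == "name":
            out.append(("name", m.group("name")))
        elif m.lastgroup == "arrow":
            out.append(("arrow", m.group("arrow")))
        else:
            out.append(("sym", m.group("sym")))
    return out


class _Tokens:
    def __init__(self, toks):
        self.toks = toks
        self.i = 0

    def peek(self, k=0):
        j = self.i + k
        return self.toks[j] if j < len(self.toks) else (None, None)

    def next(self):
        t = self.peek()
        self.i += 1
        return t

    def expect(self, kind, value=None):
        t = self.next()
        if t[0] != kind or (value is not None and t[1] != value):
            raise ParseError(f"expected {value or kind}, got {t[1]!r}")
        return t

    def done(self):
        return self.i >= len(self.toks)


# ---------------------------------------------------------------------------
# Expressions
# ---------------------------------------------------------------------------

def eval_expr(text_or_tokens, env: dict) -> float:
    """Evaluate a numeric expression with + - * / ^ and parameter names."""
    ts = (_Tokens(_tokenize(text_or_tokens))
          if isinstance(text_or_tokens, str) else text_or_tokens)

    def primary():
        kind, val = ts.next()
        if kind == "num":
            return float(val)
        if kind == "name":
            if val not in env:
                raise ParseError(f"undefined parameter {val!r}")
            return float(env[val])
        if kind == "sym" and val == "(":
            v = expr()
            ts.expect("sym", ")")
            return v
        raise ParseError(f"bad expression token {val!r}")

    # unary minus binds looser than ^ (so -a^2 == -(a^2)); the exponent
    # itself may carry a sign (2^-3)
    def factor():
        if ts.peek() == ("sym", "-"):
            ts.next()
            return -factor()
        if ts.peek() == ("sym", "+"):
            ts.next()
            return factor()
        return power()

    def power():
        v = primary()
        if ts.peek() == ("sym", "^"):
            ts.next()
            return v ** factor()
        return v

    def term():
        v = factor()
        while ts.peek()[0] == "sym" and ts.peek()[1] in "*/":
            op = ts.next()[1]
            rhs = factor()
            v = v * rhs if op == "*" else v / rhs
        return v

    def expr():
        v = term()
        while ts.peek()[0] == "sym" and ts.peek()[1] in "+-":
            op = ts.next()[1]
            rhs = term()
            v = v + rhs if op == "+" else v - rhs
        return v

    v = expr()
    if isinstance(text_or_tokens, str) and not ts.done():
        raise ParseError(f"trailing tokens in expression {text_or_tokens!r}")
    return v


# ---------------------------------------------------------------------------
# Pattern / species strings
# ---------------------------------------------------------------------------

def _parse_molecule(ts: _Tokens) -> Molecule:
    (_, name) = ts.expect("name")
    ts.expect("sym", "(")
    comps = []
    if ts.peek() != ("sym", ")"):
        while True:
            (_, cname) = ts.expect("name")
            state = None
            bond = None
            while ts.peek()[0] == "sym" and ts.peek()[1] in "~!":
                sym = ts.next()[1]
                if sym == "~":
                    kind, val = ts.next()
                    if kind not in ("name", "num"):
                        raise ParseError(f"bad state after ~: {val!r}")
                    state = val
                else:
                    kind, val = ts.next()
                    if kind == "num":
                        bond = int(val)
                    elif (kind, val) == ("sym", "+"):
                        bond = "+"
                    elif (kind, val) == ("sym", "?"):
                        bond = "?"
                    else:
                        raise ParseError(f"bad bond after !: {val!r}")
            comps.append(Component(cname, state, bond))
            if ts.peek() == ("sym", ","):
                ts.next()
                continue
            break
    ts.expect("sym", ")")
    return Molecule(name, comps)


def _parse_complex(ts: _Tokens) -> SiteGraph:
    mols = [_parse_molecule(ts)]
    while ts.peek() == ("sym", "."):
        ts.next()
        mols.append(_parse_molecule(ts))
    return SiteGraph(mols)


def parse_pattern(text: str) -> SiteGraph:
    """Parse one dotted complex/pattern string, e.g. ``A(b!1).B(a!1,c~P)``."""
    ts = _Tokens(_tokenize(text))
    g = _parse_complex(ts)
    if not ts.done():
        raise ParseError(f"trailing tokens in pattern {text!r}")
    return g


def _at_molecule(ts: _Tokens) -> bool:
    return ts.peek()[0] == "name" and ts.peek(1) == ("sym", "(")


def _parse_side(ts: _Tokens):
    """Parse ``P1 + P2 + ...`` (or ``0``); stops before the rate expression."""
    pats = []
    if ts.peek() == ("num", "0") and not (ts.peek(1) == ("sym", "(")):
        ts.next()
        return pats
    pats.append(_parse_complex(ts))
    while ts.peek() == ("sym", "+") and ts.peek(1)[0] == "name" \
            and ts.peek(2) == ("sym", "("):
        ts.next()
        pats.append(_parse_complex(ts))
    return pats


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_BLOCKS = ("parameters", "molecule types", "seed species", "species",
           "observables", "reaction rules", "population maps", "config")


def read_model(text: str) -> ModelDocument:
    """Parse a model file; reversible rules are split into two unidirectional
    rules (suffixes ``f`` and ``r``); parameter expressions are evaluated."""
    doc = ModelDocument()
    block = None
    rule_idx = 0
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            low = line.lower()
            if low.startswith("begin "):
                name = low[6:].strip()
                if name == "model":
                    continue
                if name not in _BLOCKS:
                    raise ParseError(f"unknown block {name!r}")
                block = name
                continue
            if low.startswith("end "):
                block = None
                continue
            if block is None:
                raise ParseError("statement outside any block")
            if block == "parameters":
                parts = line.split(None, 1)
                if len(parts) != 2:
                    raise ParseError("parameter lines are `name expression`")
                doc.parameters[parts[0]] = eval_expr(parts[1], doc.parameters)
            elif block == "molecule types":
                _read_molecule_type(doc, line)
            elif block in ("seed species", "species"):
                _read_seed(doc, line)
            elif block == "observables":
                _read_observable(doc, line)
            elif block == "reaction rules":
                rule_idx = _read_rule(doc, line, rule_idx)
            elif block == "population maps":
                _read_population_map(doc, line)
            elif block == "config":
                parts = line.split(None, 1)
                key = parts[0]
                val = parts[1] if len(parts) > 1 else ""
                try:
                    doc.config[key] = eval_expr(val, doc.parameters)
                except ParseError:
                    doc.config[key] = val
        except ParseError as e:
            raise ParseError(str(e), line_no, line) from None
    _mark_population_molecules(doc)
    doc.validate()
    return doc


def _read_molecule_type(doc, line):
    is_pop = False
    if line.endswith(" population"):
        is_pop = True
        line = line[: -len(" population")].rstrip()
    ts = _Tokens(_tokenize(line))
    (_, name) = ts.expect("name")
    ts.expect("sym", "(")
    comps = []
    if ts.peek() != ("sym", ")"):
        while True:
            (_, cname) = ts.expect("name")
            states = []
            while ts.peek() == ("sym", "~"):
                ts.next()
                kind, val = ts.next()
                if kind not in ("name", "num"):
                    raise ParseError(f"bad state {val!r}")
                states.append(val)
            comps.append((cname, tuple(states) if states else None))
            if ts.peek() == ("sym", ","):
                ts.next()
                continue
            break
    ts.expect("sym", ")")
    if not ts.done():
        raise ParseError("trailing tokens in molecule type")
    if name in doc.molecule_types:
        raise ParseError(f"molecule type {name} declared twice")
    doc.molecule_types[name] = MoleculeType(name, comps, is_pop)


def _read_seed(doc, line):
    ts = _Tokens(_tokenize(line))
    g = _parse_complex(ts)
    rest = ts.toks[ts.i:]
    if not rest:
        raise ParseError("seed species needs an initial count")
    count = eval_expr(_Tokens(rest), doc.parameters)
    doc.seeds.append((g, count))


def _read_observable(doc, line):
    ts = _Tokens(_tokenize(line))
    (_, kind) = ts.expect("name")
    (_, name) = ts.expect("name")
    pats = []
    while _at_molecule(ts):
        pats.append(_parse_complex(ts))
        if ts.peek() == ("sym", ","):
            ts.next()
    if not ts.done():
        raise ParseError("trailing tokens in observable")
    doc.observables.append(Observable(kind, name, pats))


def _read_rule(doc, line, rule_idx):
    ts = _Tokens(_tokenize(line))
    name = None
    # a rule label is everything before a ':' that precedes the first '(';
    # labels like "11f" tokenize as several tokens and are rejoined here
    for k in range(ts.i, len(ts.toks)):
        if ts.toks[k] == ("sym", "("):
            break
        if ts.toks[k] == ("sym", ":"):
            name = "".join(t[1] for t in ts.toks[:k])
            ts.i = k + 1
            break
    lhs = _parse_side(ts)
    kind, arrow = ts.next()
    if kind != "arrow":
        raise ParseError(f"expected -> or <->, got {arrow!r}")
    rhs = _parse_side(ts)
    rates_toks = ts.toks[ts.i:]
    # split on top-level commas
    groups, depth, cur = [], 0, []
    for t in rates_toks:
        if t == ("sym", "(",):
            depth += 1
        elif t == ("sym", ")"):
            depth -= 1
        if t == ("sym", ",") and depth == 0:
            groups.append(cur)
            cur = []
        else:
            cur.append(t)
    groups.append(cur)
    rule_idx += 1
    base = name if name is not None else f"R{rule_idx}"

    def rate_of(toks):
        if not toks:
            raise ParseError("rule is missing a rate")
        rname = toks[0][1] if (len(toks) == 1 and toks[0][0] == "name") else None
        return eval_expr(_Tokens(list(toks)), doc.parameters), rname

    if arrow == "->":
        if len(groups) != 1:
            raise ParseError("unidirectional rule takes one rate")
        k, rname = rate_of(groups[0])
        doc.rules.append(Rule(base, lhs, rhs, k, rate_name=rname))
    else:
        if len(groups) != 2:
            raise ParseError("reversible rule takes two rates `kf, kr`")
        kf, fname = rate_of(groups[0])
        kr, rname = rate_of(groups[1])
        doc.rules.append(Rule(base + "f", lhs, rhs, kf, rate_name=fname))
        doc.rules.append(Rule(base + "r",
                              [g.copy() for g in rhs],
                              [g.copy() for g in lhs],
                              kr, rate_name=rname))
    return rule_idx


def _read_population_map(doc, line):
    ts = _Tokens(_tokenize(line))
    structured = _parse_complex(ts)
    ts.expect("arrow", "->")
    target = _parse_complex(ts)
    if len(target.molecules) != 1 or target.molecules[0].components:
        raise ParseError("population-map target must be a zero-component "
                         "molecule, e.g. pop_X()")
    rest = ts.toks[ts.i:]
    if not rest:
        raise ParseError("population map needs a lumping rate constant")
    k_lump = eval_expr(_Tokens(rest), doc.parameters)
    doc.population_maps.append(
        PopulationMap(structured, target.molecules[0].name, k_lump))


def _mark_population_molecules(doc: ModelDocument):
    """Set is_population on every molecule instance; move population seeds
    into the counter table."""
    def mark(graph):
        for mol in graph.molecules:
            mt = doc.molecule_types.get(mol.name)
            if mt is not None and mt.is_population:
                mol.is_population = True

    for g, _ in doc.seeds:
        mark(g)
    for r in doc.rules:
        for g in r.reactants + r.products:
            mark(g)
        for mol in r.new_molecules:   # copies made before marking
            mt = doc.molecule_types.get(mol.name)
            if mt is not None and mt.is_population:
                mol.is_population = True
    for o in doc.observables:
        for g in o.patterns:
            mark(g)
    particle_seeds = []
    for g, n in doc.seeds:
        if len(g.molecules) == 1 and g.molecules[0].is_population:
            doc.pop_seeds.append((g.molecules[0].name, n))
        else:
            particle_seeds.append((g, n))
    doc.seeds = particle_seeds


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_model(doc: ModelDocument) -> str:
    """Serialize a model (or hybrid model) deterministically."""
    out = ["begin model"]
    if doc.parameters:
        out.append("begin parameters")
        for k, v in doc.parameters.items():
            out.append(f"  {k} {v:.12g}")
        out.append("end parameters")
    out.append("begin molecule types")
    for mt in doc.molecule_types.values():
        out.append("  " + mt.to_string())
    out.append("end molecule types")
    if doc.seeds or doc.pop_seeds:
        out.append("begin seed species")
        for g, n in doc.seeds:
            out.append(f"  {g.to_string()} {n:.12g}")
        for name, n in doc.pop_seeds:
            out.append(f"  {name}() {n:.12g}")
        out.append("end seed species")
    if doc.observables:
        out.append("begin observables")
        for o in doc.observables:
            pats = " ".join(p.to_string() for p in o.patterns)
            out.append(f"  {o.kind} {o.name} {pats}".rstrip())
        out.append("end observables")
    if doc.rules:
        out.append("begin reaction rules")
        for r in doc.rules:
            lhs = " + ".join(p.to_string() for p in r.reactants) or "0"
            rhs = " + ".join(p.to_string() for p in r.products) or "0"
            out.append(f"  {r.name}: {lhs} -> {rhs}  {r.rate:.12g}")
        out.append("end reaction rules")
    if doc.population_maps:
        out.append("begin population maps")
        for pm in doc.population_maps:
            out.append(f"  {pm.structured.to_string()} -> "
                       f"{pm.unstructured_name}()  {pm.k_lump:.12g}")
        out.append("end population maps")
    if doc.config:
        out.append("begin config")
        for k, v in doc.config.items():
            if isinstance(v, float):
                out.append(f"  {k} {v:.12g}")
            else:
                out.append(f"  {k} {v}")
        out.append("end config")
    out.append("end model")
    return "\n".join(out) + "\n"
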