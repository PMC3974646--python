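# File formats

## Model files (BNGL subset)

UTF-8 text; `#` starts a comment; blocks are delimited by
`begin <name>` / `end <name>`, optionally wrapped in `begin model` /
`end model`.  Grammar sketch (whitespace-separated tokens):

```
model        := block*
block        := parameters | "molecule types" | "seed species"
              | observables | "reaction rules" | "population maps" | config

parameters   : lines of   NAME expr
expr         := numbers, parameter names, + - * / ^, parentheses
                (unary minus binds looser than ^; scientific notation ok)

molecule types : lines of  NAME "(" [comp ("," comp)*] ")" ["population"]
comp          := NAME ("~" STATE)*            # declared states

seed species  : lines of  complex expr        # concrete species + count
observables   : lines of  ("Molecules"|"Species") NAME complex+
reaction rules: lines of  [label ":"] side ("->"|"<->") side rate [, rate]
side          := "0" | complex ("+" complex)*
population maps: lines of  complex "->" NAME "()" expr     # k_lump

complex       := molecule ("." molecule)*
molecule      := NAME "(" [site ("," site)*] ")"
site          := NAME ["~" STATE] ["!" (INT | "+" | "?")]
```

Bond labels pair within one dotted complex.  `!+` means bound to an
unspecified partner, `!?` bound or unbound; an omitted site or state is
unconstrained.  The `population` keyword marks a zero-component counter
molecule type; the `population maps` block is this package's dialect for
declaring the structured-species -> counter mapping together with the
lumping rate constant (the reference tool expresses the same information
as ordinary rules inside a configuration file — the content is
equivalent, the framing differs).  `config` lines are free-form
`key value` pairs (`t_end`, `n_steps`, ...).

## Network files

```
begin species
  <index> <canonical species string> <initial count>
  ...
end species
begin reactions
  <index> <reactant indices, comma-sep or 0> <product indices> \
      <rate constant> <multiplicity> <symmetry>   # <rule name>
  ...
end reactions
```

`multiplicity` is the embedding-tuple count of the reaction;
the effective mass-action coefficient is `rate * multiplicity /
symmetry` with ordered-pair counting (`n*(n-1)` for an identical
reactant pair).

## Trajectories (gdat)

Tab/space-separated text: a `# time <obs1> <obs2> ...` header line, then
one row per sample time.  The optional firing summary (CLI
`--firings-out`) is JSON with total, mapping and null-event counts plus
per-rule firings.
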