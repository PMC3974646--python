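# Trivalent-ligand bivalent-receptor (TLBR) aggregation model.
#
# A trivalent ligand crosslinks bivalent cell-surface receptors; near the
# solution-gel phase boundary a system-spanning aggregate forms, so the
# reaction network is infinite and only network-free simulation applies.
# Free ligand and free receptor are present in large excess and are the two
# population-lumping candidates for the hybrid model.
#
# Rates are per site pair, per second (already volume-scaled for the f = 1
# cell-scale counts below); crosslinking strength places the system in the
# solution-gel coexistence regime.

begin model

begin parameters
  L0     4.2e6      # ligands per cell
  R0     1.1e6      # receptors per cell
  kp1    1.0e-9     # ligand capture from solution (per r-l site pair)
  kp2    3.0e-8     # crosslinking by surface-attached ligand
  koff   0.01       # bond dissociation
  k_lump 1e4
end parameters

begin molecule types
  L(r,r,r)
  R(l,l)
  pop_L() population
  pop_R() population
end molecule types

begin seed species
  L(r,r,r) L0
  R(l,l) R0
end seed species

begin observables
  Molecules RBound   R(l!+)
  Molecules LFree    L(r,r,r)
end observables

begin reaction rules
  1: L(r,r,r) + R(l) -> L(r!1,r,r).R(l!1)          kp1
  2: L(r,r,r!+) + R(l) -> L(r!1,r,r!+).R(l!1)      kp2
  3: L(r,r!+,r!+) + R(l) -> L(r!1,r!+,r!+).R(l!1)  kp2
  4: L(r!1).R(l!1) -> L(r) + R(l)                  koff
end reaction rules

begin population maps
  L(r,r,r) -> pop_L()  k_lump
  R(l,l) -> pop_R()  k_lump
end population maps

begin config
  t_end 500
  n_steps 100
end config

end model
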