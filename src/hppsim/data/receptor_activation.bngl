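# Simple receptor activation model.
#
# A ligand L binds a receptor R carrying two ligand-dependent tyrosines.
# Phospho-y1 recruits the adaptor A, which is activated (phosphorylated) at
# the receptor and then recruits B; phospho-y2 recruits B directly; B
# recruits C.  A, B and C also associate in the cytosol, so complexes of
# A, B and C that exclude the receptor exist in solution.
#
# The rule set expands to 56 species (48 receptor-containing) and 287
# unidirectional reactions.  The eight receptor-free species (free L, free
# A in both phospho-forms, free B, free C, and the cytosolic complexes
# A~P.B, B.C, A~P.B.C) are the population-lumping set for the hybrid model.

begin model

begin parameters
  L0     10000
  R0     300
  A0     3000
  B0     3000
  C0     3000
  kpL    1e-4      # ligand-receptor association, per molecule per second
  kmL    0.02
  pR1    1.0       # ligand-dependent phosphorylation of y1
  dR1    0.5
  pR2    1.0
  dR2    0.5
  kpA    1e-4      # A recruitment to phospho-y1
  kmA    0.3
  pA     1.0       # receptor-mediated A activation
  dA     0.02
  kpB    1e-4      # B recruitment to phospho-y2
  kmB    0.1
  kpC    1e-4      # C binding to B
  kmC    0.1
  kpAB   1e-4      # B binding to activated A
  kmAB   0.1
  k_lump 1e4
end parameters

begin molecule types
  L(r)
  R(l,y1~U~P,y2~U~P)
  A(r,s~U~P,b)
  B(a,c)
  C(b)
  pop_L() population
  pop_A_U() population
  pop_A_P() population
  pop_B() population
  pop_C() population
  pop_APB() population
  pop_BC() population
  pop_APBC() population
end molecule types

begin seed species
  L(r) L0
  R(l,y1~U,y2~U) R0
  A(r,s~U,b) A0
  B(a,c) B0
  C(b) C0
end seed species

begin observables
  Molecules LigBound  R(l!+)
  Molecules RecPhos1  R(y1~P!?)
  Molecules RecPhos2  R(y2~P!?)
  Molecules ActiveA   A(s~P)
  Molecules BoundC    C(b!+)
  Molecules FreeL     L(r)
end observables

begin reaction rules
  1:  L(r) + R(l) <-> L(r!1).R(l!1)                 kpL, kmL
  2:  R(l!+,y1~U) -> R(l!+,y1~P)                    pR1
  3:  R(y1~P) -> R(y1~U)                            dR1
  4:  R(l!+,y2~U) -> R(l!+,y2~P)                    pR2
  5:  R(y2~P) -> R(y2~U)                            dR2
  6:  R(y1~P) + A(r) <-> R(y1~P!1).A(r!1)           kpA, kmA
  7:  A(r!+,s~U) -> A(r!+,s~P)                      pA
  8:  A(s~P,b) -> A(s~U,b)                          dA
  9:  R(y2~P) + B(a) <-> R(y2~P!1).B(a!1)           kpB, kmB
  10: B(c) + C(b) <-> B(c!1).C(b!1)                 kpC, kmC
  11: A(s~P,b) + B(a) <-> A(s~P,b!1).B(a!1)         kpAB, kmAB
end reaction rules

begin population maps
  L(r) -> pop_L()  k_lump
  A(r,s~U,b) -> pop_A_U()  k_lump
  A(r,s~P,b) -> pop_A_P()  k_lump
  B(a,c) -> pop_B()  k_lump
  C(b) -> pop_C()  k_lump
  A(r,s~P,b!1).B(a!1,c) -> pop_APB()  k_lump
  B(a,c!1).C(b!1) -> pop_BC()  k_lump
  A(r,s~P,b!1).B(a!1,c!2).C(b!2) -> pop_APBC()  k_lump
end population maps

begin config
  t_end 100
  n_steps 200
end config

end model
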