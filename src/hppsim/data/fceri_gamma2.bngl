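# FceRI signaling, gamma2 variant.
#
# A bivalent ligand (chemically crosslinked IgE dimer) aggregates FceRI
# receptors; within receptor dimers the Src-family kinase Lyn
# transphosphorylates the beta and gamma ITAMs of the partner receptor,
# phospho-gamma recruits Syk, and Syk is transactivated in dimers.  The
# gamma2 variant carries *two* identical gamma phosphorylation sites per
# receptor, which inflates the network to 3744 species and 58 276
# reactions.  Rate parameters follow the published model's orders of
# magnitude (per-molecule units at the f = 1 cell-scale counts below).

begin model

begin parameters
  Lig0  6.0e6
  Rec0  4.0e5
  Lyn0  2.8e4
  Syk0  4.0e5
  kp1   1.3e-7    # ligand capture
  km1   0.0
  kp2   2.5e-7    # receptor crosslinking
  km2   0.01
  kpL   5.0e-7    # constitutive Lyn-beta association
  kmL   2.0
  kpLs  1.0e-7    # Lyn SH2 - phospho-beta association
  kmLs  0.12
  kpS   6.0e-8    # Syk tSH2 - phospho-gamma association
  kmS   0.13
  pLb   3.0       # beta transphos by constitutive Lyn
  pLg   1.0       # gamma transphos by constitutive Lyn
  pLbs  10.0      # beta transphos by SH2-anchored Lyn
  pLgs  3.0
  pLS   3.0       # Syk linker transphos by constitutive Lyn
  pLSs  10.0
  pSS   10.0      # Syk activation loop transphos by Syk
  pSSs  20.0      # ... by activated Syk
  dm    2.0       # dephosphorylation, receptor-proximal
  dc    0.3       # dephosphorylation, cytosolic Syk
  k_lump 1e4
end parameters

begin molecule types
  Lig(l,l)
  Lyn(u,sh2)
  Syk(tsh2,l~Y~pY,a~Y~pY)
  Rec(a,b~Y~pY,g~Y~pY,g~Y~pY)
  pop_Lig() population
  pop_Lyn() population
  pop_Syk_YY() population
  pop_Syk_pY() population
  pop_Syk_Yp() population
  pop_Syk_pp() population
end molecule types

begin seed species
  Lig(l,l) Lig0
  Lyn(u,sh2) Lyn0
  Syk(tsh2,l~Y,a~Y) Syk0
  Rec(a,b~Y,g~Y,g~Y) Rec0
end seed species

begin observables
  Molecules LynFree   Lyn(u,sh2)
  Molecules RecPbeta  Rec(b~pY!?)
  Molecules RecPgamma Rec(g~pY!?)
  Molecules SykAct    Syk(a~pY!?)
  Molecules RecSyk    Rec(g!1).Syk(tsh2!1)
end observables

begin reaction rules
  1:  Rec(a) + Lig(l,l) <-> Rec(a!1).Lig(l!1,l)        kp1, km1
  2:  Rec(a) + Lig(l,l!+) <-> Rec(a!1).Lig(l!1,l!+)    kp2, km2
  3:  Rec(b~Y) + Lyn(u,sh2) <-> Rec(b~Y!1).Lyn(u!1,sh2)  kpL, kmL
  4:  Lig(l!1,l!2).Lyn(u!3,sh2).Rec(a!2,b~Y!3).Rec(a!1,b~Y) -> Lig(l!1,l!2).Lyn(u!3,sh2).Rec(a!2,b~Y!3).Rec(a!1,b~pY)  pLb
  5:  Lig(l!1,l!2).Lyn(u!3,sh2).Rec(a!2,b~Y!3).Rec(a!1,g~Y) -> Lig(l!1,l!2).Lyn(u!3,sh2).Rec(a!2,b~Y!3).Rec(a!1,g~pY)  pLg
  6:  Rec(b~pY) + Lyn(u,sh2) <-> Rec(b~pY!1).Lyn(u,sh2!1)  kpLs, kmLs
  7:  Lig(l!1,l!2).Lyn(u,sh2!3).Rec(a!2,b~pY!3).Rec(a!1,b~Y) -> Lig(l!1,l!2).Lyn(u,sh2!3).Rec(a!2,b~pY!3).Rec(a!1,b~pY)  pLbs
  8:  Lig(l!1,l!2).Lyn(u,sh2!3).Rec(a!2,b~pY!3).Rec(a!1,g~Y) -> Lig(l!1,l!2).Lyn(u,sh2!3).Rec(a!2,b~pY!3).Rec(a!1,g~pY)  pLgs
  9:  Rec(g~pY) + Syk(tsh2) <-> Rec(g~pY!1).Syk(tsh2!1)  kpS, kmS
  10: Lig(l!1,l!2).Lyn(u!3,sh2).Rec(a!2,b~Y!3).Rec(a!1,g~pY!4).Syk(tsh2!4,l~Y) -> Lig(l!1,l!2).Lyn(u!3,sh2).Rec(a!2,b~Y!3).Rec(a!1,g~pY!4).Syk(tsh2!4,l~pY)  pLS
  11: Lig(l!1,l!2).Lyn(u,sh2!3).Rec(a!2,b~pY!3).Rec(a!1,g~pY!4).Syk(tsh2!4,l~Y) -> Lig(l!1,l!2).Lyn(u,sh2!3).Rec(a!2,b~pY!3).Rec(a!1,g~pY!4).Syk(tsh2!4,l~pY)  pLSs
  12: Lig(l!1,l!2).Syk(tsh2!3,a~Y).Rec(a!2,g~pY!3).Rec(a!1,g~pY!4).Syk(tsh2!4,a~Y) -> Lig(l!1,l!2).Syk(tsh2!3,a~Y).Rec(a!2,g~pY!3).Rec(a!1,g~pY!4).Syk(tsh2!4,a~pY)  pSS
  13: Lig(l!1,l!2).Syk(tsh2!3,a~pY).Rec(a!2,g~pY!3).Rec(a!1,g~pY!4).Syk(tsh2!4,a~Y) -> Lig(l!1,l!2).Syk(tsh2!3,a~pY).Rec(a!2,g~pY!3).Rec(a!1,g~pY!4).Syk(tsh2!4,a~pY)  pSSs
  14: Rec(b~pY) -> Rec(b~Y)  dm
  15: Rec(g~pY) -> Rec(g~Y)  dm
  16: Syk(tsh2!+,l~pY) -> Syk(tsh2!+,l~Y)  dm
  17: Syk(tsh2!+,a~pY) -> Syk(tsh2!+,a~Y)  dm
  18: Syk(tsh2,l~pY) -> Syk(tsh2,l~Y)  dc
  19: Syk(tsh2,a~pY) -> Syk(tsh2,a~Y)  dc
end reaction rules

begin population maps
  Lig(l,l) -> pop_Lig()  k_lump
end population maps

begin config
  t_end 2400
  n_steps 100
end config

end model
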