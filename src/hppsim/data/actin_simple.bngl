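# Actin polymerization with ADF/cofilin-mediated severing.
#
# Filaments are linear chains of actin subunits (barbed site b bound to the
# pointed site p of the next subunit).  Monomers add at either filament end
# in the ATP state; polymerized subunits hydrolyse ATP (~T) to ADP-Pi (~P)
# and release phosphate to reach ADP (~D); ADF/cofilin binds ADP subunits
# and severs the filament on the pointed side of a decorated subunit.
# Free ATP-monomer and free ADF exist in large excess — the two
# population-lumping candidates.  Chain length is unbounded, so the encoded
# reaction network is infinite.

begin model

begin parameters
  A0         1.0e6     # actin monomers per cell (ATP-loaded)
  ADF0       2.0e5     # ADF/cofilin per cell
  k_onb      1.0e-6    # barbed-end monomer addition (per pair)
  k_onp      1.3e-7    # pointed-end monomer addition
  k_offb_T   1.4
  k_offb_P   1.1
  k_offb_D   7.2
  k_offp_T   0.8
  k_offp_P   0.3
  k_offp_D   0.25
  k_hyd      0.3       # ATP hydrolysis on polymerized subunits
  k_pi       0.1       # phosphate release
  k_exch     0.1       # nucleotide exchange on free monomer (D -> T)
  k_adf_on   1.0e-6
  k_adf_off  0.1
  k_adf_offm 1.0       # ADF release from a free monomer
  k_sev      0.2       # severing at a decorated subunit
  k_lump     1e4
end parameters

begin molecule types
  A(b,p,ad,n~T~P~D)
  ADF(a)
  pop_A() population
  pop_ADF() population
end molecule types

begin seed species
  A(b,p,ad,n~T) A0
  ADF(a) ADF0
end seed species

begin observables
  Molecules Polymerized A(b!+)
  Molecules FreeMonoT   A(b,p,ad,n~T)
  Molecules ADFBound    ADF(a!+)
end observables

begin reaction rules
  1:  A(b) + A(p,b,ad,n~T) -> A(b!1).A(p!1,b,ad,n~T)                 k_onb
  2:  A(p) + A(b,p,ad,n~T) -> A(p!1).A(b!1,p,ad,n~T)                 k_onp
  3:  A(p!1,b,ad,n~T).A(b!1) -> A(p,b,ad,n~T) + A(b)                 k_offb_T
  4:  A(p!1,b,ad,n~P).A(b!1) -> A(p,b,ad,n~P) + A(b)                 k_offb_P
  5:  A(p!1,b,ad,n~D).A(b!1) -> A(p,b,ad,n~D) + A(b)                 k_offb_D
  6:  A(b!1,p,ad,n~T).A(p!1) -> A(b,p,ad,n~T) + A(p)                 k_offp_T
  7:  A(b!1,p,ad,n~P).A(p!1) -> A(b,p,ad,n~P) + A(p)                 k_offp_P
  8:  A(b!1,p,ad,n~D).A(p!1) -> A(b,p,ad,n~D) + A(p)                 k_offp_D
  9:  A(b!+,n~T) -> A(b!+,n~P)                                       k_hyd
  10: A(b,p!+,n~T) -> A(b,p!+,n~P)                                   k_hyd
  11: A(b!+,n~P) -> A(b!+,n~D)                                       k_pi
  12: A(b,p!+,n~P) -> A(b,p!+,n~D)                                   k_pi
  13: A(b,p,ad,n~D) -> A(b,p,ad,n~T)                                 k_exch
  14: A(b,p,ad,n~P) -> A(b,p,ad,n~D)                                 k_pi
  15: A(ad,n~D,b!+) + ADF(a) -> A(ad!1,n~D,b!+).ADF(a!1)             k_adf_on
  16: A(ad,n~D,b,p!+) + ADF(a) -> A(ad!1,n~D,b,p!+).ADF(a!1)         k_adf_on
  17: A(ad!1,b!+).ADF(a!1) -> A(ad,b!+) + ADF(a)                     k_adf_off
  18: A(ad!1,b,p!+).ADF(a!1) -> A(ad,b,p!+) + ADF(a)                 k_adf_off
  19: ADF(a!1).A(ad!1,p!2).A(b!2) -> ADF(a!1).A(ad!1,p) + A(b)       k_sev
  20: A(b,p,ad!1,n~D).ADF(a!1) -> A(b,p,ad,n~D) + ADF(a)             k_adf_offm
  21: A(p!1,b,ad!2,n~D).ADF(a!2).A(b!1) -> A(p,b,ad!2,n~D).ADF(a!2) + A(b)  k_offb_D
end reaction rules

begin population maps
  A(b,p,ad,n~T) -> pop_A()  k_lump
  ADF(a) -> pop_ADF()  k_lump
end population maps

begin config
  t_end 1000
  n_steps 100
end config

end model
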