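# Standard transformed Gibbs energies of formation, pH 7, 298.15 K (Thauer convention).
# Aqueous solutes referenced to 1 M, gases to 1 bar.  Chlorobenzene congener rows are
# back-calculated from published net reaction energies of the hydrogenolytic ladder
# (Dolfing-convention compilation) anchored at HCB = +47.20 kJ/mol with
# Cl- = -131.26 and H+(pH 7) = -39.87; only differences within balanced reactions are
# physically meaningful.
# table_version: 1
name,phase,dGf0_prime_kJ_per_mol,formula,charge,source
H2O,liquid-water,-237.18,H2O,0,Thauer-compilation
H+,proton-pH7,-39.87,H,1,transformed RT*ln(1e-7) at 298.15 K
H2,gas,0.0,H2,0,element reference
bicarbonate,aqueous,-586.85,CHO3,-1,Thauer-compilation
acetate,aqueous,-369.41,C2H3O2,-1,Thauer-compilation
propionate,aqueous,-361.08,C3H5O2,-1,Thauer-compilation
lactate,aqueous,-517.81,C3H5O3,-1,Thauer-compilation (see docs/methods.md on the lactate reaction)
Cl-,aqueous,-131.26,Cl,-1,CRC standard
HCB,aqueous,47.20,C6Cl6,0,anchor (back-calculated ladder)
PeCB,aqueous,46.93,C6HCl5,0,back-calculated ladder
"1,2,3,5-TeCB",aqueous,113.06,C6H2Cl4,0,back-calculated ladder
"1,3,5-TCB",aqueous,189.19,C6H3Cl3,0,back-calculated ladder
"1,3-DCB",aqueous,284.72,C6H4Cl2,0,back-calculated ladder
"1,4-DCB",aqueous,284.72,C6H4Cl2,0,back-calculated ladder
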