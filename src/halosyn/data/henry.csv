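# Dimensionless Henry constants kcc = C_gas / C_aq at equilibrium.
# 25 C values from standard air-water partitioning compilations (H / RT);
# 80 C values (headspace-GC incubation temperature) are van't Hoff-style
# extrapolations and are order-of-magnitude estimates only.
# table_version: 1
compound,kcc_25C,kcc_80C,n_chlorines,molar_mass_g_per_mol
HCB,0.026,0.21,6,284.78
PeCB,0.030,0.24,5,250.34
"1,2,3,5-TeCB",0.040,0.32,4,215.89
"1,3,5-TCB",0.078,0.62,3,181.45
"1,3-DCB",0.106,0.85,2,147.00
"1,4-DCB",0.097,0.78,2,147.00
H2,52.0,69.0,0,2.016
CO,42.0,56.0,0,28.01
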