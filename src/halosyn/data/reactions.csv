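# Fermentative (hydrogenogenic) and dechlorinating (hydrogen-consuming) reactions of the
# co-culture system.  Stoichiometry: products positive, reactants negative.
# All reactions are element- and charge-balanced; the H+ coefficient needed for balance is
# always written explicitly even where condensed textbook forms omit it.
name,role,stoichiometry
lactate_oxidation,hydrogenogenic,lactate:-1;H2O:-2;acetate:1;bicarbonate:1;H+:1;H2:2
propionate_oxidation,hydrogenogenic,propionate:-1;H2O:-3;acetate:1;bicarbonate:1;H+:1;H2:3
acetate_oxidation,hydrogenogenic,acetate:-1;H2O:-4;bicarbonate:2;H+:1;H2:4
hcb_to_pecb,hydrogen-consuming,HCB:-1;H2:-1;PeCB:1;H+:1;Cl-:1
pecb_to_tecb,hydrogen-consuming,"PeCB:-1;H2:-1;1,2,3,5-TeCB:1;H+:1;Cl-:1"
tecb_to_tcb,hydrogen-consuming,"1,2,3,5-TeCB:-1;H2:-1;1,3,5-TCB:1;H+:1;Cl-:1"
tcb_to_13dcb,hydrogen-consuming,"1,3,5-TCB:-1;H2:-1;1,3-DCB:1;H+:1;Cl-:1"
tcb_to_14dcb,hydrogen-consuming,"1,3,5-TCB:-1;H2:-1;1,4-DCB:1;H+:1;Cl-:1"
hcb_to_dcb,hydrogen-consuming,"HCB:-1;H2:-4;1,3-DCB:1;H+:4;Cl-:4"
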