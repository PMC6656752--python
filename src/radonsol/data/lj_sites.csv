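# Nonbonded parameters for every atomic site type used in the simulations.
# epsilon: LJ well depth (kcal/mol); sigma: LJ diameter (nm); charge: partial
# charge (e) exactly as published for the study's force field; mass (amu) is a
# standard atomic/united-atom mass added here (not part of the published table).
# O_W/H_W: SPC/E water oxygen/hydrogen. C_e/H_e and C_b/H_b: hexane end (CH3)
# and backbone (CH2) carbons/hydrogens. C, O=C, O-H, H: carboxyl group of the
# fatty acids. CH2/CH3: united-atom fatty-acid chain carbons. Na/Cl/Ca: ions.
name,epsilon,sigma,charge,mass
O_W,0.155,0.317,-0.847,15.9994
H_W,0.000,0.179,0.423,1.008
C_e,0.078,0.363,-0.270,12.011
C_b,0.056,0.358,-0.180,12.011
H_e,0.024,0.238,0.009,1.008
H_b,0.035,0.238,0.009,1.008
C,0.081,0.390,0.750,12.011
O=C,0.156,0.305,-0.550,15.9994
O-H,0.184,0.302,-0.610,15.9994
H,0.000,0.179,0.009,1.008
CH2,0.091,0.395,-0.180,14.0266
CH3,0.194,0.375,-0.270,15.0345
Na,0.046,0.251,1.000,22.9898
Cl,0.150,0.404,-1.000,35.453
Ca,0.023,0.324,2.000,40.078
Rn,0.541,0.453,0.000,222.0176
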