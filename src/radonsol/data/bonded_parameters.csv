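# Bonded (intramolecular) parameters for the flexible molecules.
# EXTERNAL-CONSTANT DATA: representative values taken from the published
# all-atom (hexane) and united-atom (fatty acid) force fields this package's
# molecule set is based on; they are not fitted here and can be overridden by
# passing an alternative file to radonsol.forcefield.load_bonded_parameters.
#
# kind=bond:     a,b = site types;     p1 = k_b (kcal/mol/nm^2), p2 = b0 (nm)
#                energy U = k_b * (b - b0)^2
# kind=angle:    a,b,c = site types;   p1 = k_t (kcal/mol/rad^2), p2 = theta0 (deg)
#                energy U = k_t * (theta - theta0)^2
# kind=dihedral: a,b = types of the two CENTRAL atoms; p1 = k_phi (kcal/mol),
#                p2 = multiplicity n, p3 = phase delta (deg)
#                energy U = k_phi * (1 + cos(n*phi - delta))
kind,a,b,c,p1,p2,p3
bond,C_e,C_b,,22250,0.1530,
bond,C_b,C_b,,22250,0.1530,
bond,C_e,H_e,,30900,0.1111,
bond,C_b,H_b,,30900,0.1111,
bond,CH3,CH2,,26000,0.1526,
bond,CH2,CH2,,26000,0.1526,
bond,CH2,C,,26000,0.1522,
bond,C,O=C,,57000,0.1229,
bond,C,O-H,,45000,0.1364,
bond,O-H,H,,55300,0.0960,
angle,C_b,C_b,C_b,58.0,113.5,
angle,C_e,C_b,C_b,58.0,113.5,
angle,H_e,C_e,C_b,34.6,110.1,
angle,H_b,C_b,C_b,34.6,110.1,
angle,H_b,C_b,C_e,34.6,110.1,
angle,H_e,C_e,H_e,35.5,108.4,
angle,H_b,C_b,H_b,35.5,109.0,
angle,CH3,CH2,CH2,63.0,112.4,
angle,CH2,CH2,CH2,63.0,112.4,
angle,CH2,CH2,C,63.0,112.4,
angle,CH2,C,O=C,80.0,120.4,
angle,CH2,C,O-H,70.0,110.3,
angle,O=C,C,O-H,80.0,121.0,
angle,C,O-H,H,55.0,113.0,
dihedral,C_b,C_b,,0.19,3,0
dihedral,C_e,C_b,,0.16,3,0
dihedral,CH2,CH2,,1.40,3,0
dihedral,CH3,CH2,,1.40,3,0
dihedral,CH2,C,,0.50,6,180
dihedral,C,O-H,,1.00,2,180
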