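# Reference full-scale simulation summaries (NPT, 298 K, 1 bar) for the
# liquids studied: nearest-neighbour distance r_nn (nm), equilibrium mass
# density density (g/cm^3), and equilibrium dissolved-radon concentration
# c_rn with standard error (g/cm^3) from droplet-in-radon-gas runs at
# production scale (10^3-10^4 molecules, >= 10 ns).  The radon row is the
# pure radon gas used as the reference phase; its density is the D_Rn that
# normalizes every solubility.  water_Qp / water_Q0 / water_Qm are SPC/E
# water with the oxygen partial charge scaled by +15% / 0 / -15%.
# c_rn empty where not measured; water_Qp dissolved radon was indistinguishable
# from zero.
liquid,r_nn,density,c_rn,c_rn_err
water_Qp,0.298,1.058,0.0,0.0
water_Q0,0.310,0.995,6.451e-4,0.007e-4
water_Qm,0.352,0.852,2.093e-3,0.023e-3
water_5_NaCl,,,1.372e-3,0.019e-3
water_1.9_CaCl2,,,1.464e-3,0.016e-3
hexane,0.446,0.662,1.333e-2,0.058e-2
butyric_acid,0.451,1.014,2.161e-2,0.090e-2
capric_acid,0.463,0.921,2.260e-2,0.093e-2
radon_gas,0.453,9.36e-3,,
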