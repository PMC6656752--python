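# Bundled gamma-spectroscopy exposure records: per-run radon concentration in
# the sample back-extrapolated to sealing time from the 214Pb and 214Bi
# gamma lines (c_pb, c_bi, Bq/cm^3) and the ambient radon activity
# concentration during exposure (d_rn, Bq/cm^3).  sample_density (g/cm^3) is
# the assumed bulk density used for the mass->volume normalization.
# Liquids: isotonic 0.9% NaCl solution, oleic acid (C18H34O2), linoleic acid
# (C18H32O2); exposures at 295.2 K and 1001 mbar.
liquid,c_pb,c_pb_err,c_bi,c_bi_err,d_rn,d_rn_err,sample_density
saline_0.9_NaCl,0.11,0.08,0.09,0.07,3.97,0.11,1.000
saline_0.9_NaCl,0.17,0.01,0.17,0.01,6.39,0.21,1.000
saline_0.9_NaCl,0.13,0.01,0.14,0.01,6.20,0.20,1.000
oleic_acid,3.65,0.08,3.62,0.08,2.12,0.07,0.895
oleic_acid,4.05,0.08,3.96,0.08,2.88,0.08,0.895
oleic_acid,5.32,0.08,5.26,0.08,3.76,0.10,0.895
linoleic_acid,7.76,0.22,7.36,0.22,3.91,0.11,0.900
linoleic_acid,8.86,0.22,8.36,0.22,2.88,0.08,0.900
linoleic_acid,6.73,0.21,7.07,0.21,3.76,0.10,0.900
linoleic_acid,7.15,0.21,6.90,0.21,3.76,0.10,0.900
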