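# Stopped-flow k_obs for atDGD2 binding to POPC/MGDG/POPG (70:20:10) LUVs,
# 25 C, 50 mM sodium phosphate pH 7.4, 200 mM NaCl.  Post-mixing protein
# concentration 0.78 uM.  lipid_total_uM is the post-mixing total lipid
# concentration; only the outer leaflet (factor 0.5) is accessible.
lipid_total_uM,kobs_s1,se_s1
45.5,1.57,0.01
91,1.68,0.01
136.5,2.37,0.01
182,3.13,0.02
227.5,4.09,0.03
273,4.97,0.04
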