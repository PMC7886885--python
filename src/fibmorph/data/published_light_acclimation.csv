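condition,compartment,occupancy_pct,occupancy_sd_pct,n_cells
LL,plastid,33.7,1.8,3
LL,mitochondrion,3.9,0.2,3
LL,pyrenoid,2.4,0.6,3
HL,plastid,24.7,6.7,3
HL,mitochondrion,6.6,0.7,3
HL,pyrenoid,3.2,0.9,3
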