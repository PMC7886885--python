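species,plastid_volume_um3,plastid_volume_sd_um3,pyrenoid_volume_um3,pyrenoid_volume_sd_um3,pyrenoid_plastid_pct,pyrenoid_plastid_pct_sd,pyrenoid_sv_ratio_per_um,pyrenoid_sv_ratio_sd_per_um
Phaeodactylum,11.0,0.3,0.8,0.1,7.1,1.2,20.6,6.0
Emiliania,5.9,1.8,0.5,0.2,9.3,1.4,12.3,2.6
Micromonas,0.5,0.2,0.05,0.03,7.2,1.2,15.1,2.4
Symbiodinium,63.5,9.5,1.8,0.3,2.8,0.2,4.7,2.3
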