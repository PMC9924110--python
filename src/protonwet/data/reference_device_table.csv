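device,tps_spr,tps_spr_sd,measured_spr,measured_spr_sd,percent_diff,percent_diff_sd,wet_diff_mm,wet_diff_sd_mm
MOLDCARE cushion,0.080,0.006,0.101,0.009,-20.9,4.6,-0.9,0.4
Vac-Lok bag,0.052,0.003,0.070,0.002,-26.0,2.9,-1.3,0.4
Dental putty,1.519,0.031,1.517,0.051,0.2,5.4,0.0,0.5
Thin sheets (16 layers),0.171,0.002,0.200,0.003,-14.4,0.4,-0.2,0.0
Thick sheets (16 layers),0.129,0.011,0.150,0.011,-14.0,1.8,-0.5,0.1
Bite block (foam),0.212,,0.241,,-12.1,,-0.4,
Bite block (handle),0.364,,0.485,,-24.9,,-0.3,
BoS insert (head),0.790,,1.100,,-28.2,,-0.9,
BoS insert (body),0.122,,0.189,,-35.1,,-2.2,
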