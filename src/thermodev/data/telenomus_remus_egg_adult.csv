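species,stage,temperature_c,dev_time_days,se_days,n
telenomus_remus,egg_adult,15,52.70,0.41,20
telenomus_remus,egg_adult,20,21.09,0.11,20
telenomus_remus,egg_adult,25,12.49,0.03,20
telenomus_remus,egg_adult,30,8.26,0.02,20
telenomus_remus,egg_adult,35,8.10,0.03,20
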