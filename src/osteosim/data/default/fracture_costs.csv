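fracture_type,age_band_lower,kind,cost_eur
hip,50,acute,11000
hip,65,acute,12000
hip,75,acute,13000
hip,85,acute,14000
hip,50,continuing,500
hip,65,continuing,1500
hip,75,continuing,3000
hip,85,continuing,5000
vertebral,50,acute,4000
vertebral,65,acute,4300
vertebral,75,acute,4600
vertebral,85,acute,5000
vertebral,50,continuing,120
vertebral,65,continuing,120
vertebral,75,continuing,120
vertebral,85,continuing,120
wrist,50,acute,1800
wrist,65,acute,1900
wrist,75,acute,2000
wrist,85,acute,2100
wrist,50,continuing,0
wrist,65,continuing,0
wrist,75,continuing,0
wrist,85,continuing,0
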