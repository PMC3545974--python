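fracture_type,age,ratio
hip,52,0.55000000000000004
hip,57,0.55625000000000002
hip,62,0.5625
hip,67,0.56874999999999998
hip,72,0.57499999999999996
hip,77,0.58125000000000004
hip,82,0.58750000000000002
hip,87,0.59375
hip,92,0.59999999999999998
vertebral,52,0.59999999999999998
vertebral,57,0.60624999999999996
vertebral,62,0.61250000000000004
vertebral,67,0.61875000000000002
vertebral,72,0.625
vertebral,77,0.63124999999999998
vertebral,82,0.63749999999999996
vertebral,87,0.64375000000000004
vertebral,92,0.65000000000000002
wrist,52,0.25
wrist,57,0.25624999999999998
wrist,62,0.26250000000000001
wrist,67,0.26874999999999999
wrist,72,0.27500000000000002
wrist,77,0.28125
wrist,82,0.28749999999999998
wrist,87,0.29375000000000001
wrist,92,0.29999999999999999
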