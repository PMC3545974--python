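fracture_type,age,rr
hip,52,2
hip,57,2
hip,62,2
hip,67,2
hip,72,2
hip,77,2
hip,82,2
hip,87,2
hip,92,2
vertebral,52,2.6000000000000001
vertebral,57,2.6000000000000001
vertebral,62,2.6000000000000001
vertebral,67,2.6000000000000001
vertebral,72,2.6000000000000001
vertebral,77,2.6000000000000001
vertebral,82,2.6000000000000001
vertebral,87,2.6000000000000001
vertebral,92,2.6000000000000001
wrist,52,1.3
wrist,57,1.3
wrist,62,1.3
wrist,67,1.3
wrist,72,1.3
wrist,77,1.3
wrist,82,1.3
wrist,87,1.3
wrist,92,1.3
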