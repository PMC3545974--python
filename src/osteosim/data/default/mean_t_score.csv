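gender,age,mean_t_score
female,52,-1
female,57,-1.3
female,62,-1.6000000000000001
female,67,-1.906818181818182
female,72,-2.2000000000000002
female,77,-2.4713068181818185
female,82,-2.7000000000000002
female,87,-2.8718750000000002
female,92,-3
male,52,-0.5
male,57,-0.80000000000000004
male,62,-1.1000000000000001
male,67,-1.4068181818181817
male,72,-1.7
male,77,-1.9713068181818183
male,82,-2.2000000000000002
male,87,-2.3718750000000002
male,92,-2.5000000000000004
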