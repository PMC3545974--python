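gender,age,q6
female,50,0.002
female,51,0.0020260740740740742
female,52,0.0021019259259259259
female,53,0.0022239999999999998
female,54,0.0023887407407407412
female,55,0.002592592592592593
female,56,0.0028319999999999999
female,57,0.0031034074074074076
female,58,0.0034032592592592595
female,59,0.0037280000000000008
female,60,0.0040740740740740737
female,61,0.004437925925925925
female,62,0.004816
female,63,0.0052047407407407415
female,64,0.0056005925925925928
female,65,0.0060000000000000001
female,66,0.006428714879467997
female,67,0.006914274314214465
female,68,0.0074558004987531163
female,69,0.0080524156275976738
female,70,0.008703241895261846
female,71,0.0094074014962593541
female,72,0.010164016625103906
female,73,0.010972209476309227
female,74,0.011831102244389028
female,75,0.012739817123857022
female,76,0.013697476309226932
female,77,0.014703201995012467
female,78,0.015756116375727349
female,79,0.016855341645885286
female,80,0.017999999999999999
female,81,0.019491336658354112
female,82,0.021521865336658352
female,83,0.023927610972568573
female,84,0.026544598503740649
female,85,0.029208852867830426
female,86,0.03175639900249376
female,87,0.034023261845386538
female,88,0.035845466334164584
female,89,0.037059037406483787
female,90,0.037499999999999999
female,91,0.037499999999999999
female,92,0.037499999999999999
female,93,0.037499999999999999
female,94,0.037499999999999999
female,95,0.037499999999999999
female,96,0.037499999999999999
female,97,0.037499999999999999
female,98,0.037499999999999999
female,99,0.037499999999999999
female,100,0.037499999999999999
female,101,0.037499999999999999
female,102,0.037499999999999999
female,103,0.037499999999999999
female,104,0.037499999999999999
female,105,0.037499999999999999
male,50,0.0025000000000000001
male,51,0.0025441185185185182
male,52,0.0026406941798941801
male,53,0.002786057142857143
male,54,0.0029765375661375665
male,55,0.0032084656084656084
male,56,0.0034781714285714292
male,57,0.0037819851851851856
male,58,0.0041162370370370375
male,59,0.004477257142857142
male,60,0.0048613756613756619
male,61,0.0052649227513227514
male,62,0.0056842285714285724
male,63,0.0061156232804232807
male,64,0.0065554370370370374
male,65,0.0070000000000000001
male,66,0.0074766139183769752
male,67,0.0080142167761938481
male,68,0.0086115930846223845
male,69,0.0092675273548343609
male,70,0.0099808040980015507
male,71,0.010750207825295725
male,72,0.011574523047888655
male,73,0.012452534276952112
male,74,0.013383026023657872
male,75,0.014364782799177703
male,76,0.01539658911468338
male,77,0.016477229481346677
male,78,0.017605488410339366
male,79,0.018780150412833214
male,80,0.02
male,81,0.021566050955414015
male,82,0.023669808917197454
male,83,0.02614579617834395
male,84,0.028828535031847131
male,85,0.031552547770700642
male,86,0.034152356687898087
male,87,0.036462484076433127
male,88,0.038317452229299366
male,89,0.039551783439490451
male,90,0.040000000000000001
male,91,0.040000000000000001
male,92,0.040000000000000001
male,93,0.040000000000000001
male,94,0.040000000000000001
male,95,0.040000000000000001
male,96,0.040000000000000001
male,97,0.040000000000000001
male,98,0.040000000000000001
male,99,0.040000000000000001
male,100,0.040000000000000001
male,101,0.040000000000000001
male,102,0.040000000000000001
male,103,0.040000000000000001
male,104,0.040000000000000001
male,105,0.040000000000000001
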