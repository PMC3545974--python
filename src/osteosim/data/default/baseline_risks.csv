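gender,fracture_type,age,annual_risk
female,hip,52,0.00040000000000000002
female,hip,57,0.0006756249999999999
female,hip,62,0.0012999999999999999
female,hip,67,0.0024385482283464572
female,hip,72,0.0044000000000000003
female,hip,77,0.0082206093803491968
female,hip,82,0.014
female,hip,87,0.021790217391304351
female,hip,92,0.031999999999999994
female,vertebral,52,0.0016000000000000001
female,vertebral,57,0.0024007415254237289
female,vertebral,62,0.0035999999999999999
female,vertebral,67,0.0053100297511720152
female,vertebral,72,0.0074999999999999997
female,vertebral,77,0.010103087419056429
female,vertebral,82,0.012999999999999999
female,vertebral,87,0.015936141304347822
female,vertebral,92,0.019
female,wrist,52,0.0040000000000000001
female,wrist,57,0.0045000000000000005
female,wrist,62,0.0050000000000000001
female,wrist,67,0.0054999999999999997
female,wrist,72,0.0060000000000000001
female,wrist,77,0.0065535714285714286
female,wrist,82,0.0070000000000000001
female,wrist,87,0.0072589285714285716
female,wrist,92,0.0074000000000000003
male,hip,52,0.00022000000000000003
male,hip,57,0.00037581640624999996
male,hip,62,0.00073124999999999991
male,hip,67,0.0013869243048720474
male,hip,72,0.0025300000000000001
male,hip,77,0.0047782292023279714
male,hip,82,0.0082249999999999997
male,hip,87,0.012937941576086957
male,hip,92,0.019199999999999995
male,vertebral,52,0.00096000000000000002
male,vertebral,57,0.0014554495497881355
male,vertebral,62,0.0022049999999999999
male,vertebral,67,0.0032855809085376845
male,vertebral,72,0.0046874999999999998
male,vertebral,77,0.0063775739332793705
male,vertebral,82,0.0082874999999999997
male,vertebral,87,0.010258890964673912
male,vertebral,92,0.01235
male,wrist,52,0.001
male,wrist,57,0.0011531250000000001
male,wrist,62,0.0013125000000000001
male,wrist,67,0.0014781249999999998
male,wrist,72,0.0016500000000000002
male,wrist,77,0.0018431919642857143
male,wrist,82,0.0020125
male,wrist,87,0.0021323102678571428
male,wrist,92,0.0022200000000000002
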