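gender,age,q6
female,50,0.0040000000000000001
female,51,0.0041670673076923074
female,52,0.004367307692307692
female,53,0.0045992788461538467
female,54,0.0048615384615384623
female,55,0.0051526442307692315
female,56,0.0054711538461538461
female,57,0.0058156250000000013
female,58,0.0061846153846153856
female,59,0.0065766826923076924
female,60,0.0069903846153846162
female,61,0.0074242788461538469
female,62,0.0078769230769230765
female,63,0.0083468750000000001
female,64,0.0088326923076923088
female,65,0.0093329326923076925
female,66,0.0098461538461538482
female,67,0.010370913461538463
female,68,0.010905769230769233
female,69,0.011449278846153847
female,70,0.012
female,71,0.012607732803720208
female,72,0.013315538074016664
female,73,0.014111864561131563
female,74,0.01498516101530711
female,75,0.015923876186785507
female,76,0.016916458825808948
female,77,0.017951357682619646
female,78,0.019017021507459795
female,79,0.020101899050571592
female,80,0.021194439062197246
female,81,0.022283090292578956
female,82,0.023356301491958924
female,83,0.024402521410579345
female,84,0.025410198798682424
female,85,0.026367782406510363
female,86,0.027263720984305365
female,87,0.028086463282309626
female,88,0.028824458050765358
female,89,0.02946615403991475
female,90,0.029999999999999999
female,91,0.030472784401529993
female,92,0.030937216638012605
female,93,0.031390626844188557
female,94,0.031830345154798552
female,95,0.032253701704583311
female,96,0.032658026628283557
female,97,0.033040650060639991
female,98,0.033398902136393321
female,99,0.033730112990284278
female,100,0.034031612757053561
female,101,0.034300731571441895
female,102,0.034534799568189993
female,103,0.034731146882038565
female,104,0.034887103647728332
female,105,0.03500000000000001
male,50,0.0030000000000000001
male,51,0.0031634545454545457
male,52,0.0033530909090909093
male,53,0.0035678181818181815
male,54,0.0038065454545454548
male,55,0.0040681818181818189
male,56,0.0043516363636363639
male,57,0.004655818181818182
male,58,0.004979636363636364
male,59,0.0053220000000000003
male,60,0.005681818181818182
male,61,0.006058
male,62,0.0064494545454545447
male,63,0.0068550909090909088
male,64,0.0072738181818181816
male,65,0.0077045454545454561
male,66,0.0081461818181818163
male,67,0.0085976363636363646
male,68,0.0090578181818181808
male,69,0.0095256363636363646
male,70,0.01
male,71,0.010517959859385218
male,72,0.011111599084368869
male,73,0.011772375327011118
male,74,0.01249174623937214
male,75,0.013261169473512099
male,76,0.014072102681491174
male,77,0.014916003515369524
male,78,0.015784329627207327
male,79,0.016668538669064748
male,80,0.017560088293001964
male,81,0.018450436151079136
male,82,0.019331039895356443
male,83,0.020193357177894052
male,84,0.021028845650752123
male,85,0.021828962965990843
male,86,0.022585166775670372
male,87,0.023288914731850886
male,88,0.023931664486592546
male,89,0.024504873691955524
male,90,0.025000000000000001
male,91,0.02544889421795897
male,92,0.025888059076548287
male,93,0.026315930113052416
male,94,0.026730942864755813
male,95,0.027131532868942942
male,96,0.027516135662898254
male,97,0.027883186783906208
male,98,0.028231121769251265
male,99,0.028558376156217882
male,100,0.028863385482090519
male,101,0.029144585284153632
male,102,0.029400411099691673
male,103,0.029629298465989114
male,104,0.029829682920330402
male,105,0.029999999999999999
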