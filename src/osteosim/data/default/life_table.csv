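gender,age,q6
female,50,0.00066720452054125357
female,51,0.00074109853075121634
female,52,0.00082317979776802552
female,53,0.00091435623664792853
female,54,0.0010156366292524144
female,55,0.0011281418735581417
female,56,0.0012531174977125081
female,57,0.0013919475834102135
female,58,0.0015461702602477256
female,59,0.001717494951948062
female,60,0.0019078215770256257
female,61,0.0021192619309409189
female,62,0.0023541635044717069
female,63,0.0026151360243878985
female,64,0.0029050810381040515
female,65,0.0032272249044708046
female,66,0.0035851555990138451
female,67,0.003982863794674385
female,68,0.0044247887395388874
female,69,0.0049158695224948978
female,70,0.0054616023978059092
female,71,0.0060681049321699154
female,72,0.0067421878452779138
female,73,0.0074914355400426125
female,74,0.0083242964650628304
female,75,0.0092501846238345342
female,76,0.01027959374809817
female,77,0.011424225893241213
female,78,0.012697136500275152
female,79,0.014112898312248379
female,80,0.015687786946590343
female,81,0.017439991426178469
female,82,0.019389853583292482
female,83,0.021560141001185973
female,84,0.023976359085951304
female,85,0.026667109017100676
female,86,0.029664499776098752
female,87,0.033004624288498263
female,88,0.036728112060459117
female,89,0.040880773713560803
female,90,0.045514356758396324
female,91,0.050687437129136814
female,92,0.056466477901619072
female,93,0.062927095922643894
female,94,0.070155589798075124
female,95,0.078250800334709325
female,96,0.087326399414715539
female,97,0.097513738999908006
female,98,0.10896544425349441
female,99,0.12186001301256033
female,100,0.13640780383315554
female,101,0.15285898398484277
female,102,0.1715143164777253
female,103,0.19274018414161787
female,104,0.216990161365889
female,105,0.24483713001969143
male,50,0.0010782781563716259
male,51,0.0011953320698185887
male,52,0.0013251013605360962
male,53,0.0014689692130895882
male,54,0.0016284697192374686
male,55,0.0018053044440466959
male,56,0.0020013608340337941
male,57,0.002218732677544577
male,58,0.0024597428528165821
male,59,0.0027269686277010541
male,60,0.0030232698073690001
male,61,0.0033518200630542339
male,62,0.0037161418167036553
male,63,0.0041201451041142922
male,64,0.0045681708937272969
male,65,0.0050650394008820987
male,66,0.0056161040094044878
male,67,0.0062273114956280518
male,68,0.0069052693463513837
male,69,0.0076573210743483555
male,70,0.0084916305659231694
male,71,0.0094172766484222903
male,72,0.010444359246261192
male,73,0.011584118707714253
male,74,0.012849070138743479
male,75,0.014253154883705155
male,76,0.015811911657503841
male,77,0.017542670274544814
male,78,0.019464771455766416
male,79,0.021599816850845999
male,80,0.023971954220644576
male,81,0.026608203727517266
male,82,0.029538832534590886
male,83,0.032797786494889181
male,84,0.036423189719235638
male,85,0.040457925387505478
male,86,0.044950314503571009
male,87,0.049954913659476352
male,88,0.055533458650563472
male,89,0.061755988518737204
male,90,0.068702195095680541
male,91,0.076463057557947911
male,92,0.085142841682841031
male,93,0.094861572166574648
male,94,0.10575812787604866
male,95,0.11799417125055256
male,96,0.13175921583407368
male,97,0.14727727985816819
male,98,0.16481580375192217
male,99,0.1846978892723139
male,100,0.20731956985247979
male,101,0.23317499199427372
male,102,0.26289460284384836
male,103,0.29730591040663379
male,104,0.33753615029132256
male,105,0.38519978520935505
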