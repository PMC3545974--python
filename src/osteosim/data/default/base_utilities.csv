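gender,age,utility
all,50,0.83999999999999997
all,51,0.83275402435269696
all,52,0.82560133824324389
all,53,0.81854317954370093
all,54,0.8115807861261285
all,55,0.80471539586258689
all,56,0.79794824662513653
all,57,0.79128057628583781
all,58,0.78471362271675094
all,59,0.7782486237899362
all,60,0.77188681737745424
all,61,0.76562944135136513
all,62,0.75947773358372928
all,63,0.75343293194660699
all,64,0.74749627431205889
all,65,0.74166899855214474
all,66,0.7359523425389255
all,67,0.73034754414446135
all,68,0.72485584124081226
all,69,0.71947847170003909
all,70,0.7142166733942017
all,71,0.70907168419536093
all,72,0.70404474197557687
all,73,0.6991370846069096
all,74,0.69434994996141997
all,75,0.68968457591116805
all,76,0.68514220032821416
all,77,0.68072406108461869
all,78,0.67643139605244207
all,79,0.67226544310374448
all,80,0.66822744011058643
all,81,0.66431862494502825
all,82,0.6605402354791301
all,83,0.65689350958495241
all,84,0.65337968513455558
all,85,0.65000000000000002
all,86,0.64671640250993068
all,87,0.64349254306707548
all,88,0.64033221265461948
all,89,0.63723920225574737
all,90,0.63421730285364397
all,91,0.63127030543149409
all,92,0.62840200097248244
all,93,0.62561618045979384
all,94,0.62291663487661308
all,95,0.62030715520612512
all,96,0.61779153243151463
all,97,0.61537355753596645
all,98,0.61305702150266528
all,99,0.61084571531479603
all,100,0.60874342995554365
all,101,0.60675395640809271
all,102,0.60488108565562815
all,103,0.60312860868133455
all,104,0.60150031646839686
all,105,0.59999999999999998
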