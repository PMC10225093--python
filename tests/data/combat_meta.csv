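site,group,age,sex
0,NMOSD,48.146962756862735,0
2,HC,40.810948833866696,1
1,MS,43.46943278427981,0
1,MS,47.575458710062485,1
1,MS,22.514130161732,0
2,HC,36.16394540371238,0
0,MS,34.35552814848646,1
2,HC,32.3334658210799,1
0,NMOSD,36.69829298527979,0
0,NMOSD,57.93929573481275,1
1,NMOSD,29.610026611681082,0
2,NMOSD,51.61934025509777,1
2,MS,19.80556274061034,1
2,NMOSD,35.9813796401707,0
2,MS,41.95303678126007,1
2,HC,47.03466797631134,0
1,NMOSD,48.53471895751426,0
0,MS,49.520166822399105,0
2,HC,35.81529913301875,0
1,MS,34.4517784880252,1
1,NMOSD,50.29571057508585,0
1,HC,37.70434810142062,0
0,MS,24.69176411994494,1
2,HC,26.400553431958233,0
2,NMOSD,28.966572567980663,1
1,MS,45.96592892864517,0
1,HC,41.70910883284678,1
2,HC,48.28582424881322,1
1,MS,34.87296824396159,1
1,NMOSD,41.90247629292057,0
1,NMOSD,47.50708472760804,0
0,MS,36.28784152335714,1
0,HC,45.481302850688934,0
1,NMOSD,32.05688870720019,1
2,MS,35.64335384121914,0
0,NMOSD,35.41914527202005,1
2,HC,25.649924252931523,1
2,HC,45.84366976942698,0
0,NMOSD,34.36717191756731,0
1,NMOSD,40.14992942473225,1
0,MS,45.768959906870904,0
2,NMOSD,45.35837411235933,1
2,NMOSD,47.984621307673436,0
1,MS,38.81817418588692,1
0,NMOSD,34.920420255470155,1
2,HC,39.04338146912321,0
1,HC,19.751986792503644,1
2,NMOSD,22.634650330922952,0
2,MS,24.12760465174717,1
2,HC,28.03303806878222,0
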