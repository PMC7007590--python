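lat1,lon1,lat2,lon2,distance_m
-8.1915351767,162.6459297323,-64.5024335772,130.8283593204,6731564.1913
36.4709235291,74.9593983937,-44.7520617072,-164.374669374,15028548.4209
-35.8813253721,178.6027986197,-52.0688096091,177.5953538924,1800394.6037
-12.7287055819,89.5342316793,-56.3493067004,34.5904360682,6715884.2287
18.9103783993,53.2174289014,-78.1762061553,18.7849220114,10993008.7553
8.4550891555,80.9301369263,12.6009933659,-112.599343218,17245425.6067
57.053110813,-4.2599482089,-65.6663896982,26.3593664019,13852546.3723
31.5309362813,55.9689828215,34.8537738436,149.2727489536,8358726.1706
-52.0637805278,25.1503602541,-64.9509292224,-134.6286196018,6911963.8694
49.4255857089,-13.7296544303,-69.1899388102,-112.016702508,15324620.4992
3.7364287407,5.2792458824,62.2870078202,-105.924363023,10714706.0780
-2.3792333677,-170.2686579545,-66.945894803,161.9132847491,7482521.8983
-8.6579929922,142.9380155207,48.6679608882,96.8399771068,7783830.1166
6.0392391745,43.3699951608,-48.3854082238,-46.0587977631,10465285.2191
-9.2650808733,178.3355828811,56.4787145776,0.4330465075,14763468.9531
38.5006915055,-151.8859231265,-1.3424482157,-148.1299784482,4428322.6411
-1.0622950573,177.3259799721,36.6857724505,-118.4647019102,7810964.6027
51.0927012852,-135.8469157184,-63.3898306502,33.2642945464,18491395.7007
-40.0208394943,8.4224041463,-49.9051965338,116.2068606155,7809504.4310
-15.388596606,-142.3965379515,-27.096765976,124.4362102428,9552793.4924
60.0449120578,95.561045632,28.4005659528,-101.5510312616,10077855.2031
60.0890512397,83.0885273079,27.1928384135,-107.6620819103,10281191.8638
-12.4696647628,3.7857088643,15.3741837885,142.9838180744,15620192.6374
55.9444302944,104.8602670558,-35.2368013082,-48.164234559,16930840.7978
-4.3310630955,144.6855312894,70.8635469781,167.8844137963,8518830.8190
33.5676756728,-92.8790866041,66.9559325751,5.4128809252,6964806.6919
-31.2285938844,-114.3611536422,-51.0188401781,80.5442157259,10777026.8924
43.2099210956,85.7873090017,-68.5236489377,80.8017001704,12397301.0798
26.5320408098,8.5490610961,-59.4415377296,151.5570814424,15383738.6502
-0.5021734119,-12.3192065547,45.6115925933,42.821744015,7423915.0990
-8.9480614048,-139.7128425556,57.9822864332,72.2952693504,13919540.0326
15.6352270998,-40.3770391539,-77.6109986597,128.8467403617,13088461.9349
56.9725955017,-90.8349456285,6.4336119491,-66.4734326,5996319.7393
28.4540557647,23.4247988761,23.3034041959,-27.1114951232,5060749.6137
49.7612296412,-36.075524056,76.9232964853,55.719575883,4724330.7013
22.1676647981,-174.3258724898,-10.6886585723,74.2707627233,12652477.8219
-28.885015977,-81.8015232224,15.0617947962,-29.9311852271,7399390.8730
-31.8430963883,56.4163973041,-6.2238374715,108.0689605327,6057914.1125
8.607980141,64.0503784178,-19.9660222675,-27.119635698,10460850.6362
12.3333874997,124.6398719965,-59.2214583514,-18.8111108475,13988590.5378
-14.1021686162,105.9400454419,4.1566666903,-149.0438866597,11749351.8467
52.3798952137,-59.8004234426,45.5738752927,169.046185042,8193806.3983
54.721784264,171.8265076033,-19.2250905362,96.0719789673,10852934.2891
-57.8326478416,-136.9222891689,68.9406062131,-76.3182374843,14884311.6990
-7.5938371043,123.7176680441,23.0336672578,-82.8518999553,16711409.9053
40.1479958419,-158.5843507245,-20.1519246257,140.9332354291,9152233.4851
-14.2094712098,167.308565391,60.2157489227,127.1767045307,8993791.5056
-49.5729951136,19.0605678782,-72.7893046066,49.5814156272,2989416.9864
25.7964380696,-66.3360884702,-43.2549017953,-47.587849516,7882752.3043
40.9186448273,91.7673758177,12.3059118127,50.319216358,5128729.5506
-68.3280571635,174.7208947998,-31.8877198716,-32.2065583669,8670574.0217
66.6905089027,39.7934306515,4.6149937682,-31.4364365539,8715981.0546
46.0410485899,-143.4014778481,-36.7254133909,32.043908574,18904071.0236
-53.039429738,-100.2162819144,-46.6558105986,-2.0725649814,6523491.6208
-61.3070334719,77.082719333,55.1484496659,83.5965701531,12926156.5066
22.7232121496,-173.3179866144,11.4102701244,93.3584718282,9867356.7451
-0.7112568372,-41.7771187577,7.8681749572,177.1290819673,15648567.0171
-78.4353568352,-68.0884759444,74.1819997022,109.6338045816,19525444.7389
-6.5059510126,99.2772514204,52.2347172223,118.6208122497,6763612.5567
8.2399755927,-111.1934808628,70.6949139251,-10.3775825217,9539417.1048
-68.4990420728,-155.9802445521,79.5698976087,-144.1047341548,16455900.0755
52.5932321721,-84.3594420325,28.3823652912,-79.2126062424,2722031.0047
9.5090958661,-100.220817108,67.1198622637,-128.0525135443,6727500.1303
2.9591565178,-77.1429934994,-55.7437229653,-49.0189282989,6994506.1789
11.4382743224,176.978446847,-69.5913667061,-66.5822225064,12197805.3174
-71.2710526259,-129.9291769333,2.314812054,68.1025614064,12241629.3232
3.8997436336,67.6774779077,7.3545510946,-104.0164056204,18466212.1930
-52.5843864024,-4.223557452,68.8731270525,-17.1047487858,13513146.2295
-59.6532301752,-146.6350059303,21.5204193143,-79.9225565491,10823641.4974
61.4826357366,177.0407441695,-72.3081684897,34.0041965924,18039644.4440
61.7025332512,58.4664998738,72.2915990288,42.3778542382,1363694.3423
-42.5213046042,65.869145773,-38.0174550222,-70.7850197488,10069669.1327
55.431695322,-153.513229745,15.4930311334,54.4407380913,11719201.1551
-8.0874987013,90.0411971565,-54.9137870724,169.3234249067,8590644.1106
78.9904813569,-20.8343770394,52.5068383414,17.397082805,3292611.6922
45.7445941378,-177.3120917238,36.4358455733,-140.5706307129,3222725.8672
60.6965533321,97.8072422518,-32.8845407989,-151.2465927226,14257259.0094
74.8673427149,-141.1721156611,10.585031763,-4.8544559053,10066676.4007
41.5160977305,52.9477327787,22.2957828603,-51.3870561792,9514286.9663
-74.7578745279,-132.6500735709,-53.9142886705,-112.0948273709,2494920.7501
51.4575103254,66.8555061117,-20.7221315474,19.2780701688,9241470.6627
-66.4091886011,-80.6820025473,-50.6827976175,145.0421454088,6455543.9930
24.7272936335,161.1043258314,-0.0469153075,1.064801337,16539884.7288
71.5874466802,-146.8443010314,1.825251672,-56.2783284078,9832180.8050
46.221332983,139.7986154233,-30.7027302265,27.3242591867,14068418.5650
-58.2468794599,-168.6007058789,-70.7355505618,-52.6380397316,4842655.9367
-13.4801114458,-95.6736599433,-25.6675058533,-15.0100703221,8453941.7888
45.8311941287,-91.662860425,-71.8805042701,-25.7013362314,14028057.5012
-38.8197847647,36.1727211865,56.6870014779,11.8892591539,10828035.1238
34.6175958963,-39.6017170979,76.7577948878,-115.5315027157,5928223.5160
-26.2086005049,-157.1799331812,-25.7540996592,-37.8949547749,11330985.1693
-44.6646612496,-24.3953987262,-66.8100499143,152.1853838205,7639657.4543
-9.1116973496,-64.3226018426,-9.5758164456,21.1747610207,9362835.1431
-21.0497672428,148.2367402662,-19.04564525,-21.7045050124,15436947.9494
-50.2574464641,-3.8735264201,27.3623079404,89.5221971012,12526747.3703
-12.2350158264,133.5419775046,77.0019105643,-109.769307434,11974131.1699
-38.03274937,-18.6750717198,-7.5447674386,112.1404019584,12849601.0119
26.2066014478,53.7715989827,14.0342560461,172.5388502666,12043929.2534
-71.5404717253,-115.1234947499,1.2098302017,-161.250428102,8717519.3729
61.1573517346,121.2839827162,54.6323907883,15.8312809129,5603171.7114
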