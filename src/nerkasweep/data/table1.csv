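map,waterbody,population,region,catchment,migratory_ecotype,reproductive_ecotype,n,p_G,source
1,Kurilskoye Lake,Close North,"Kamchatka, Russia",Kurilskoye,sockeye,shore,24,0.90,this-study
1,Kurilskoye Lake,Far North,"Kamchatka, Russia",Kurilskoye,sockeye,shore,23,0.87,this-study
1,Kurilskoye Lake,Gavrushka Bay,"Kamchatka, Russia",Kurilskoye,sockeye,shore,24,0.71,this-study
1,Kurilskoye Lake,Khakitzin Bay,"Kamchatka, Russia",Kurilskoye,sockeye,shore,24,0.94,this-study
1,Kurilskoye Lake,Oladochnaya Bay,"Kamchatka, Russia",Kurilskoye,sockeye,shore,24,0.96,this-study
1,Kurilskoye Lake,Ozernaya,"Kamchatka, Russia",Kurilskoye,sockeye,shore,22,1.00,this-study
1,Kurilskoye Lake,South Bay,"Kamchatka, Russia",Kurilskoye,sockeye,shore,24,1.00,this-study
1,Kurilskoye Lake,Etamink River,"Kamchatka, Russia",Kurilskoye,sockeye,stream,24,0.56,this-study
1,Kurilskoye Lake,Gavrushka River,"Kamchatka, Russia",Kurilskoye,sockeye,stream,24,0.27,this-study
1,Kurilskoye Lake,Kirushutk River,"Kamchatka, Russia",Kurilskoye,sockeye,stream,24,0.27,this-study
1,Kurilskoye Lake,Vichenkiya River,"Kamchatka, Russia",Kurilskoye,sockeye,stream,21,0.17,this-study
2,Kronotsky Lake,Kronotsky Lake,"Kamchatka, Russia",Kronotskoye,kokanee,shore,12,0.75,this-study
3,Illiamna Lake,Fuel Dump Island,"Alaska, USA",Illiamna,sockeye,shore,14,0.32,this-study
3,Illiamna Lake,Knutson Bay,"Alaska, USA",Illiamna,sockeye,shore,21,0.71,this-study
3,Illiamna Lake,Woody Island,"Alaska, USA",Illiamna,sockeye,shore,20,0.28,this-study
3,Illiamna Lake,Chinkelyes Creek,"Alaska, USA",Illiamna,sockeye,stream,11,0.14,this-study
3,Illiamna Lake,Gibraltar Creek,"Alaska, USA",Illiamna,sockeye,stream,21,0.24,this-study
3,Illiamna Lake,Copper River,"Alaska, USA",Illiamna,sockeye,stream,20,0.13,this-study
4,Mezadin Lake,Meziadin Beach,"British Columbia, Canada",Nass,sockeye,shore,48,0.94,this-study
4,Mezadin Lake,Tintina Creek,"British Columbia, Canada",Nass,sockeye,stream,19,0.50,this-study
4,Mezadin Lake,Hanna Creek,"British Columbia, Canada",Nass,sockeye,stream,24,0.54,this-study
5,Gingit River,Gingit Creek,"British Columbia, Canada",Nass,sockeye,stream,23,0.17,this-study
6,Babine Lake,Pierre Creek,"British Columbia, Canada",Skeena,kokanee,stream,15,0.00,this-study
7,Tchesinkut Lake,Tchesinkut Lake,"British Columbia, Canada",Skeena,kokanee,shore,36,1.00,this-study
7,Tchesinkut Lake,Drew Creek,"British Columbia, Canada",Skeena,kokanee,stream,36,1.00,this-study
8,Cowichan Lake,Cowichan Lake,"British Columbia, Canada",Vancouver Island,kokanee,shore,3,1.00,this-study
9,Anderson-Seton Lakes,Anderson Lake,"British Columbia, Canada",Fraser,kokanee,shore,22,0.98,this-study
10,Anderson-Seton Lakes,Portage Creek,"British Columbia, Canada",Fraser,sockeye,stream,20,0.18,this-study
11,Anderson-Seton Lakes,Seton Lake,"British Columbia, Canada",Fraser,kokanee,shore,23,1.00,this-study
12,Quesnel Lake,Quesnel Lake,"British Columbia, Canada",Fraser,kokanee,shore,27,1.00,this-study
13,Nicola Lake,Upper Nicola River,"British Columbia, Canada",Fraser,kokanee,stream,24,0.19,this-study
14,Adams Lake,Momich Creek,"British Columbia, Canada",Fraser,kokanee,stream,24,0.23,this-study
14,Adams Lake,Sinmax Creek,"British Columbia, Canada",Fraser,kokanee,stream,21,0.55,this-study
15,Shuswap Lake,Eagle River,"British Columbia, Canada",Fraser,kokanee,stream,9,0.28,this-study
16,Skaha Lake,Okanagan River,"British Columbia, Canada",Columbia,sockeye,stream,33,0.02,this-study
17,Skaha Lake,Penticton Channel,"British Columbia, Canada",Columbia,kokanee,stream,19,0.08,this-study
18,Okanagan Lake,Okanagan Lake,"British Columbia, Canada",Columbia,kokanee,shore,144,0.99,this-study
18,Okanagan Lake,Mission Creek,"British Columbia, Canada",Columbia,kokanee,stream,136,0.10,this-study
19,Wood Lake,Wood Lake,"British Columbia, Canada",Columbia,kokanee,shore,48,0.92,this-study
19,Wood Lake,Middle Vernon Creek,"British Columbia, Canada",Columbia,kokanee,stream,48,0.28,this-study
20,Kalmalka Lake,Kalmalka Lake,"British Columbia, Canada",Columbia,kokanee,shore,32,0.95,this-study
20,Kalmalka Lake,Coldstream Creek,"British Columbia, Canada",Columbia,kokanee,stream,32,0.23,this-study
21,Christina Lake,Christina Lake,"British Columbia, Canada",Columbia,kokanee,shore,48,1.00,this-study
21,Christina Lake,Sanders Creek,"British Columbia, Canada",Columbia,kokanee,stream,48,0.07,this-study
22,Kootenay Lake,Kootenay Lake (West Arm),"British Columbia, Canada",Columbia,kokanee,shore,46,0.37,this-study
22,Kootenay Lake,Duhamel Creek (West Arm),"British Columbia, Canada",Columbia,kokanee,stream,32,0.19,this-study
22,Kootenay Lake,Meadow Creek (North Arm),"British Columbia, Canada",Columbia,kokanee,stream,22,0.11,this-study
23,Redfish Lake,Redfish Lake,"Idaho, USA",Columbia,sockeye,shore,99,1.00,prior-study
23,Redfish Lake,Fishhook Creek,"Idaho, USA",Columbia,kokanee,stream,34,0.10,prior-study
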