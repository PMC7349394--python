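site_id,locality,latitude,longitude,altitude,surface_area,perimeter,vegetation_grade,shoreline_vegetation_rate,concrete_revetment_rate,shore_gradient_mean,shore_gradient_sd,inflow_count,outflow_count,transparency_mean,tn_mean,nh4_mean,po4_mean
1,Shinagura,36.2923,137.9904,828,940,121,III,66.7,0.0,33.7,15.8,1,1,46.4,0.0,0.0,0.13
2,Okada-ibuka,36.2897,137.9742,776,2470,206,II,100.0,0.0,66.2,29.7,2,1,36.2,1.7,0.0,0.10
3,Shimauchi,36.2827,137.9602,848,3470,231,II,12.2,100.0,61.5,17.0,2,1,14.8,0.0,0.0,0.10
4,Misayama,36.2778,138.0091,846,180,55,II,57.4,5.2,42.4,16.2,0,1,49.3,5.0,0.0,0.10
5,Hora,36.2755,137.9929,802,590,95,II,49.2,10.8,46.3,12.5,1,1,68.8,0.0,0.0,0.10
6,Okada-ibuka,36.2768,137.9685,767,120,46,II,48.5,19.8,22.5,13.8,0,0,30.7,0.0,0.0,0.10
7,Okada-shimookada,36.2704,137.9630,736,2270,188,II,17.4,39.6,48.8,20.3,3,1,32.4,0.0,0.0,0.10
8,Okada-shimookada,36.2679,137.9578,737,650,98,II,42.5,31.5,44.5,29.3,1,1,56.9,0.0,0.0,0.13
9,Satoyamabe,36.2545,138.0268,1205,3520,237,II,57.2,9.2,42.0,25.0,2,1,53.1,1.7,0.0,0.10
10,Satoyamabe,36.2183,138.0109,835,810,120,II,31.5,39.8,54.3,26.9,4,1,>100.0,3.3,0.0,0.10
11,Nakayama,36.1941,138.0004,726,2540,215,V,48.4,53.2,67.5,26.7,2,1,83.1,1.7,0.0,0.10
12,Kotobuki-toyooka,36.1857,137.9816,646,670,106,II,66.2,72.8,56.8,29.3,3,1,66.8,6.7,0.0,0.10
13,Kotobuki-koaka,36.1695,137.9769,661,4840,268,II,40.9,59.1,47.0,19.9,4,1,37.9,0.0,0.0,0.10
14,Hirooka-yoshida,36.1564,137.9558,654,5950,333,III,63.4,43.8,24.5,14.8,4,1,77.3,0.0,0.0,0.10
15,Kataoka,36.1489,138.0155,1030,6000,305,II,43.2,26.6,51.1,22.6,2,1,>100.0,0.0,0.0,0.10
16,Kataoka,36.1374,137.9820,745,540,95,II,47.0,8.1,27.8,10.7,0,0,77.2,11.7,1.5,0.10
17,Kataoka,36.1296,137.9910,813,2020,196,II,47.5,62.3,42.1,11.1,3,1,88.4,0.0,0.0,0.10
18,Kataoka,36.1196,137.9787,734,860,134,II,81.7,0.0,24.3,18.4,2,1,>100.0,1.7,0.0,0.10
19,Sajiki,36.1149,137.9922,799,2600,231,II,61.5,41.3,31.4,20.7,2,1,83.7,0.0,0.0,0.10
20,Kakizawa,36.1078,138.0040,922,620,104,II,71.8,3.0,43.4,13.4,1,1,>100.0,1.7,0.0,0.10
21,Kaminishijo,36.0924,137.9870,781,1600,161,II,97.1,2.9,34.5,13.1,0,1,>100.0,0.0,0.0,0.10
22,Kyu-shiojiri,36.0810,137.9840,916,720,110,II,58.7,2.1,23.3,7.9,1,1,>100.0,0.0,0.0,0.10
23,Nishiseba,36.1276,137.8889,764,3780,262,II,100.0,21.0,46.2,26.0,2,1,>100.0,0.0,0.0,0.10
24,Kami-oike,36.1491,137.8616,799,2130,186,II,65.0,2.3,40.1,19.8,3,1,92.3,0.0,0.0,0.10
25,Azusagawa-azusa,36.2285,137.8381,809,1480,160,II,30.7,0.0,38.3,16.7,2,1,>100.0,0.0,0.0,0.10
26,Misato-ogura,36.2457,137.8376,744,150,64,III,100.0,0.0,9.0,3.4,1,1,>100.0,0.0,0.0,0.10
27,Misato-ogura,36.2515,137.8433,742,4860,313,II,13.9,100.0,61.9,34.2,2,1,>100.0,0.0,0.0,0.10
28,Horigane-karasugawa,36.3085,137.7797,1178,1100,149,II,14.3,100.0,52.4,18.9,1,1,97.3,1.7,0.0,0.10
29,Hotaka-kashiwabara,36.3235,137.8671,585,170,59,II,92.6,0.0,23.7,15.8,1,1,17.7,0.0,0.0,0.10
30,Hotaka-ariake,36.3525,137.8301,692,120,57,II,38.3,0.0,49.1,15.3,3,1,>100.0,0.0,0.0,0.10
31,Akashina-nakagawate,36.3448,137.9341,768,110,46,II,100.0,0.0,31.3,8.4,1,0,47.0,0.0,0.0,0.10
32,Aida,36.3633,137.9900,774,7880,502,II,96.1,0.0,64.3,37.0,4,2,39.9,0.0,0.0,0.10
33,Akashina-nanaki,36.3675,137.9211,546,1100,141,III,72.6,7.6,42.6,18.9,2,0,>100.0,0.0,0.0,0.10
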