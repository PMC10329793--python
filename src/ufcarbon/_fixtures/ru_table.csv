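ru_id,name,province,ecozone,ru_area_km2,urban_area_km2,canopy_area_km2,canopy_cover_pct
1,BC Pacific maritime,BC,Pacific maritime,200716,1991,766,38.5
2,BC Montane cordillera,BC,Montane cordillera,428955,526,136,25.8
3,AB Boreal plains,AB,Boreal plains,367539,111,32,29.0
4,AB Semiarid prairies,AB,Semiarid prairies,71203,262,17,6.6
5,AB Subhumid prairies,AB,Subhumid prairies,80577,1691,197,11.6
6,SK Boreal plains,SK,Boreal plains,164464,70,22,32.1
7,SK Semiarid prairies,SK,Semiarid prairies,154361,340,40,11.7
8,MB Subhumid prairies,MB,Subhumid prairies,64079,539,85,15.8
9,ON Boreal shield west,ON,Boreal shield west,335151,183,87,47.7
10,ON Mixedwood plains,ON,Mixedwood plains,82439,5317,1193,22.4
11,ON Boreal shield east,ON,Boreal shield east,241097,574,232,40.3
12,QC Boreal shield east,QC,Boreal shield east,600491,142,47,32.8
13,QC Mixedwood plains,QC,Mixedwood plains,27707,3240,961,29.7
14,QC Atlantic maritime,QC,Atlantic maritime,67077,217,85,39.0
15,NB Atlantic maritime,NB,Atlantic maritime,71389,512,252,49.2
16,NS Atlantic maritime,NS,Atlantic maritime,53247,337,168,50.0
17,PE Atlantic maritime,PE,Atlantic maritime,5654,70,16,22.3
18,NL Boreal shield east,NL,Boreal shield east,104740,190,83,43.8
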