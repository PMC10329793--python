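city,ru_id,external,assessment_area_ha,n_plots,carbon_storage_t,carbon_storage_se_t,seq_gross_t_yr,seq_gross_se_t_yr,canopy_area_override_ha
Halifax,16,0,69270,190,2134697,156789,118483,8228,
Ajax,10,0,6743,198,105641,18065,3547,471,
Aurora,10,0,4943,205,102981,12824,4050,418,
Bolton,10,0,1677,46,12682,4341,757,185,
Brampton,10,0,26945,196,174736,30078,7732,1130,
Caledon,10,0,478,37,13689,3468,590,128,
London,10,0,23591,383,359763,42669,12451,1145,
Markham,10,0,21269,213,229886,42226,9229,1413,
Mississauga,10,0,28801,205,202870,40786,10002,1493,
Oakville,10,0,9893,367,49724,4937,4177,390,
Pickering,10,0,4718,219,104191,13733,4242,428,
Richmond Hill,10,0,10201,208,165699,26595,7241,876,
Toronto,10,0,63727,407,1107645,99010,46741,3302,
Kelowna,2,0,21723,150,126911,19245,7713,1300,
Calgary,5,0,55032,196,183595,39072,10108,1679,
Edmonton,5,0,69985,307,615774,91284,31848,4055,
Seattle,1,1,54324,223,535261,,37817,,5499
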