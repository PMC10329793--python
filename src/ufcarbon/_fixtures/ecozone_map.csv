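ecozone,source,proxy_ecozone,storage_density,seq_rate
Pacific maritime,pooled,,,
Montane cordillera,pooled,,,
Boreal plains,forest_model,,40.0,3.0
Subhumid prairies,pooled,,,
Semiarid prairies,proxy_ecozone,Subhumid prairies,,
Boreal shield west,forest_model,,40.0,3.0
Mixedwood plains,pooled,,,
Boreal shield east,forest_model,,40.0,3.0
Atlantic maritime,pooled,,,
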