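ecozone,storage_density,seq_rate,source,note
Pacific maritime,97.4,6.9,proxy_city,Derived from the Seattle assessment
Montane cordillera,22.6,1.4,pooled,
Boreal plains,40.0,3.0,forest_model,Derived from managed-forest models
Subhumid prairies,54.7,2.9,pooled,
Semiarid prairies,54.7,2.9,proxy_city,Derived from Subhumid Prairies
Boreal shield west,40.0,3.0,forest_model,Derived from managed-forest models
Mixedwood plains,57.8,2.4,pooled,
Boreal shield east,40.0,3.0,forest_model,Derived from managed-forest models
Atlantic maritime,61.6,3.4,pooled,
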