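storage_density_t_ha,seq_rate_t_ha_yr
76.9,2.12
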