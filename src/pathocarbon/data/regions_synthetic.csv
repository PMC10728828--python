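region,cancer_cases,renewable_share,intensity_kg_per_kwh,forest_area_km2
Aachen,4804,0.462,0.4,45.5
Germany,552800,0.462,0.4,114000.0
United States,2370000,0.2,,3100000.0
China,4570000,0.27,,2200000.0
India,1190000,0.21,,720000.0
Japan,900000,0.19,,250000.0
United Kingdom,457000,0.43,,31900.0
France,483000,0.22,,170000.0
Brazil,559000,0.84,,4970000.0
World,20625588,0.2,,40600000.0
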