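class_code,class_name,area_ha
1,remnant_forest,146929.5
2,disturbed_forest,28241.54
3,savanna_grassland,113093.5
4,grassland,26716.23
5,wetland,18396.11
6,coffee_plantation,41893.27
7,farmland,94844.59
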