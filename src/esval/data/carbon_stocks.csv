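class_code,class_name,carbon_stock_t_c_per_ha
1,remnant_forest,461
2,disturbed_forest,396
3,savanna_grassland,286.8
4,grassland,286.8
5,wetland,279.5
6,coffee_plantation,259.4
7,farmland,246.5
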