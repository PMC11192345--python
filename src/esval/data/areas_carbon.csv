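class_code,class_name,area_ha
1,remnant_forest,146251.59
2,disturbed_forest,30832.15
3,savanna_grassland,28720.98
4,grassland,28720.98
5,wetland,20513.97
6,coffee_plantation,37768.27
7,farmland,90778.37
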