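class_code,class_name,category,function,original_value,adjusted_value,source_note
1,remnant_forest,regulating,erosion_control,68.50,84.31,avoided-cost study 2018 adjusted to 2023
2,disturbed_forest,regulating,erosion_control,66.17,81.39,avoided-cost study 2018 adjusted to 2023
6,coffee_plantation,regulating,erosion_control,18.52,22.78,avoided-cost study 2018 adjusted to 2023
3,savanna_grassland,regulating,erosion_control,67.46,82.98,avoided-cost study 2018 adjusted to 2023
1,remnant_forest,supporting,nutrient_cycling,922.00,1913.70,benefit transfer
2,disturbed_forest,supporting,nutrient_cycling,361.00,749.28,benefit transfer
1,remnant_forest,supporting,soil_formation,10.00,20.76,benefit transfer
2,disturbed_forest,supporting,soil_formation,10.00,20.76,benefit transfer
3,savanna_grassland,supporting,soil_formation,1.00,2.08,benefit transfer
4,grassland,supporting,soil_formation,1.00,2.08,benefit transfer
1,remnant_forest,supporting,pollination,623.07,890.32,benefit transfer
2,disturbed_forest,supporting,pollination,668.80,955.67,benefit transfer
6,coffee_plantation,supporting,pollination,939.50,1342.90,benefit transfer
3,savanna_grassland,supporting,pollination,730.00,1043.62,benefit transfer
4,grassland,supporting,pollination,730.00,1043.62,benefit transfer
7,farmland,supporting,pollination,192.84,275.68,benefit transfer
5,wetland,supporting,pollination,196.20,280.47,benefit transfer
1,remnant_forest,regulating,flood_regulation,6.00,12.45,benefit transfer
3,savanna_grassland,regulating,flood_regulation,3.00,6.23,benefit transfer
4,grassland,regulating,flood_regulation,3.00,6.23,benefit transfer
5,wetland,regulating,flood_regulation,15.00,31.13,benefit transfer
1,remnant_forest,regulating,water_treatment,87.00,180.57,benefit transfer
2,disturbed_forest,regulating,water_treatment,87.00,180.57,benefit transfer
3,savanna_grassland,regulating,water_treatment,87.00,180.57,benefit transfer
4,grassland,regulating,water_treatment,87.00,180.57,benefit transfer
5,wetland,regulating,water_treatment,1659.00,3443.30,benefit transfer
1,remnant_forest,regulating,pest_control,2.00,4.15,benefit transfer
2,disturbed_forest,regulating,pest_control,2.00,4.15,benefit transfer
6,coffee_plantation,regulating,pest_control,181.25,248.08,benefit transfer
3,savanna_grassland,regulating,pest_control,23.00,47.74,benefit transfer
4,grassland,regulating,pest_control,23.00,47.74,benefit transfer
7,farmland,regulating,pest_control,24.00,49.81,benefit transfer
1,remnant_forest,cultural,medicinal_plants,3.00,4.71,benefit transfer
2,disturbed_forest,cultural,medicinal_plants,3.00,4.71,benefit transfer
1,remnant_forest,cultural,recreation,112.00,232.46,benefit transfer
2,disturbed_forest,cultural,recreation,66.00,136.99,benefit transfer
3,savanna_grassland,cultural,recreation,2.00,4.15,benefit transfer
4,grassland,cultural,recreation,2.00,4.15,benefit transfer
5,wetland,cultural,recreation,491.00,1019.10,benefit transfer
1,remnant_forest,supporting,habitat,2.00,4.15,benefit transfer
2,disturbed_forest,supporting,habitat,2.00,4.15,benefit transfer
5,wetland,supporting,habitat,439.00,911.17,benefit transfer
1,remnant_forest,provisioning,genetic_resource,41.00,85.10,benefit transfer
2,disturbed_forest,provisioning,genetic_resource,16.00,33.21,benefit transfer
1,remnant_forest,provisioning,honey,76.00,85.74,benefit transfer
2,disturbed_forest,provisioning,forest_products,196.00,221.11,"honey, timber, charcoal, fuelwood, spice"
6,coffee_plantation,provisioning,coffee_production,3423.57,3423.57,market price and site-level production
5,wetland,provisioning,livestock_water_mulch,839.98,1102.24,"grazing, watering, milk, mulch grass; 2013 adjusted to 2023"
7,farmland,provisioning,crop_production,638.00,719.75,benefit transfer
3,savanna_grassland,provisioning,livestock_feed_forage,41.73,41.73,benefit transfer
4,grassland,provisioning,livestock_feed,11.62,12.16,benefit transfer
4,grassland,provisioning,forage,0.204,0.23,benefit transfer
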