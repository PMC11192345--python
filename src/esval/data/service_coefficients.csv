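category,function,class_code,class_name,value_usd_per_ha_yr
supporting,nutrient_cycling,1,remnant_forest,1913.70
supporting,nutrient_cycling,2,disturbed_forest,749.30
supporting,soil_formation,1,remnant_forest,20.80
supporting,soil_formation,2,disturbed_forest,20.80
supporting,soil_formation,3,savanna_grassland,2.10
supporting,soil_formation,4,grassland,2.10
supporting,pollination,1,remnant_forest,890.60
supporting,pollination,2,disturbed_forest,955.90
supporting,pollination,3,savanna_grassland,1043.40
supporting,pollination,4,grassland,1043.40
supporting,pollination,5,wetland,280.50
supporting,pollination,6,coffee_plantation,1342.90
supporting,pollination,7,farmland,275.70
supporting,habitat,1,remnant_forest,4.20
supporting,habitat,2,disturbed_forest,4.20
regulating,climate_regulation,1,remnant_forest,2484.80
regulating,climate_regulation,2,disturbed_forest,2134.40
regulating,climate_regulation,3,savanna_grassland,1545.90
regulating,climate_regulation,4,grassland,1545.90
regulating,climate_regulation,5,wetland,1506.50
regulating,climate_regulation,6,coffee_plantation,1398.20
regulating,climate_regulation,7,farmland,1328.60
regulating,erosion_control,1,remnant_forest,84.30
regulating,erosion_control,2,disturbed_forest,81.40
regulating,erosion_control,3,savanna_grassland,83.00
regulating,erosion_control,4,grassland,83.00
regulating,erosion_control,5,wetland,83.00
regulating,erosion_control,6,coffee_plantation,22.80
regulating,flood_regulation,1,remnant_forest,12.50
regulating,flood_regulation,2,disturbed_forest,4.20
regulating,flood_regulation,3,savanna_grassland,6.20
regulating,flood_regulation,4,grassland,6.20
regulating,flood_regulation,5,wetland,31.10
regulating,water_treatment,1,remnant_forest,180.60
regulating,water_treatment,2,disturbed_forest,180.60
regulating,water_treatment,3,savanna_grassland,180.60
regulating,water_treatment,4,grassland,180.60
regulating,water_treatment,5,wetland,3443.30
regulating,pest_control,1,remnant_forest,4.20
regulating,pest_control,2,disturbed_forest,4.20
regulating,pest_control,3,savanna_grassland,47.70
regulating,pest_control,4,grassland,47.70
regulating,pest_control,6,coffee_plantation,248.10
regulating,pest_control,7,farmland,49.80
provisioning,honey,1,remnant_forest,85.70
provisioning,forest_products,2,disturbed_forest,221.10
provisioning,coffee_production,6,coffee_plantation,3423.60
provisioning,livestock_water_mulch,5,wetland,1102.20
provisioning,crop_production,7,farmland,719.80
provisioning,livestock_feed_forage,3,savanna_grassland,41.70
provisioning,livestock_feed,4,grassland,12.20
provisioning,forage,4,grassland,0.20
provisioning,genetic_resource,1,remnant_forest,85.10
provisioning,genetic_resource,2,disturbed_forest,33.20
cultural,medicinal_plants,1,remnant_forest,4.70
cultural,medicinal_plants,2,disturbed_forest,4.70
cultural,recreation,1,remnant_forest,232.50
cultural,recreation,2,disturbed_forest,137.00
cultural,recreation,3,savanna_grassland,4.20
cultural,recreation,4,grassland,4.20
cultural,recreation,5,wetland,1019.10
cultural,cultural_heritage,1,remnant_forest,4.20
cultural,cultural_heritage,2,disturbed_forest,4.20
cultural,cultural_heritage,5,wetland,1828.60
cultural,cultural_heritage,6,coffee_plantation,4.20
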