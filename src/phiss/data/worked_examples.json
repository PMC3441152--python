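{
  "schema_version": "1.0",
  "worked_examples": [
    {
      "name": "iraq_1991_under5_excess_deaths",
      "parameter_id": "under5_excess_deaths",
      "raw_value": 46900,
      "expected_score": 8,
      "citation": "Iraq 1991, Gulf War and subsequent sanctions: estimated 46,900 excess deaths among children under 5, January-August 1991."
    },
    {
      "name": "niger_2005_acute_malnutrition",
      "parameter_id": "malnourished_children",
      "raw_value": 63000,
      "expected_score": 10,
      "citation": "Niger 2005 food crisis: MSF treated 63,000 children with acute malnutrition."
    },
    {
      "name": "darfur_2009_water_quality",
      "parameter_id": "water_quality_pct",
      "raw_value": 45.2,
      "expected_score": 5,
      "citation": "Nyala City, South Darfur, Sudan 2009: 45.2% of 240 sampled drinking-water sources contaminated with fecal coliforms."
    },
    {
      "name": "rwanda_1994_water_quantity",
      "parameter_id": "water_quantity_lpd",
      "raw_value": 0.2,
      "expected_score": 9,
      "citation": "Rwanda 1994: about 800,000 refugees with water availability of only 0.2 liters/person/day in the first weeks."
    },
    {
      "name": "kibeho_1994_living_space",
      "parameter_id": "inadequate_space_persons",
      "raw_value": 0,
      "expected_score": 0,
      "citation": "Kibeho camp, Rwanda 1994: 9 km^2 for up to 120,000 IDPs, about 75 m^2 per person on average, so zero persons below the 45 m^2 standard for illustration."
    },
    {
      "name": "bosnia_systematic_gbv",
      "parameter_id": "gbv_level",
      "raw_value": 4,
      "expected_score": 4,
      "citation": "Former Yugoslavia: an estimated 20,000-50,000 Bosnian women systematically raped as a means of ethnic displacement; systematic gender-based violence."
    },
    {
      "name": "haiti_2010_healthcare_disruption",
      "parameter_id": "healthcare_level",
      "raw_value": 4,
      "expected_score": 4,
      "citation": "Haiti 2010 earthquake, acute phase: all four levels of health care disrupted."
    },
    {
      "name": "haiti_2010_excess_deaths",
      "parameter_id": "excess_deaths",
      "raw_value": 222570,
      "expected_score": 9,
      "citation": "Haiti 2010 earthquake: 222,570 deaths (EM-DAT)."
    },
    {
      "name": "bangladesh_1970_cyclone_deaths",
      "parameter_id": "excess_deaths",
      "raw_value": 300000,
      "expected_score": 10,
      "citation": "Bangladesh 1970 tropical cyclone: more than 300,000 killed, the highest death toll recorded by EM-DAT 1900-2011; rubric ceiling."
    },
    {
      "name": "greece_2007_forest_fire_deaths",
      "parameter_id": "excess_deaths",
      "raw_value": 67,
      "expected_score": 1,
      "citation": "Greece 2007 forest fires: 67 deaths (EM-DAT)."
    },
    {
      "name": "pakistan_2005_earthquake_deaths",
      "parameter_id": "excess_deaths",
      "raw_value": 73338,
      "expected_score": 7,
      "citation": "Pakistan 2005 earthquake: 73,338 deaths (EM-DAT)."
    },
    {
      "name": "chile_2010_injuries",
      "parameter_id": "injury_cases",
      "raw_value": 12000,
      "expected_score": 5,
      "citation": "Chile 2010 earthquake: 12,000 injured."
    },
    {
      "name": "india_1984_chemical_injuries",
      "parameter_id": "injury_cases",
      "raw_value": 200000,
      "expected_score": 9,
      "citation": "India 1984 chemical disaster (Bhopal): 200,000 injured."
    },
    {
      "name": "haiti_2010_injuries",
      "parameter_id": "injury_cases",
      "raw_value": 300000,
      "expected_score": 10,
      "citation": "Haiti 2010 earthquake: 300,000 injured, among the highest documented acute injury counts; rubric ceiling."
    }
  ]
}
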