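# synthetic example density/nutrient table (plausible values for testing;
# not sourced from any proprietary nutrition database)
food_id,density_g_per_cm3,kcal_per_g,carb_g_per_g,protein_g_per_g,sugar_g_per_g,fat_g_per_g
mashed_potatoes,1.03,1.13,0.17,0.02,0.014,0.042
meatloaf,1.05,2.04,0.09,0.14,0.03,0.13
apple,0.84,0.52,0.14,0.003,0.10,0.002
croissant,0.35,4.06,0.46,0.08,0.11,0.21
chicken_breast,1.04,1.65,0.0,0.31,0.0,0.036
pasta_cooked,0.96,1.57,0.31,0.058,0.006,0.009
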