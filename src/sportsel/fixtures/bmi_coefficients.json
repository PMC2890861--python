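{
 "constant": 29.682,
 "gender_male": 0.364,
 "age_16_24": -2.93,
 "age_25_34": -1.625,
 "age_35_44": -1.017,
 "age_45_54": -0.575,
 "ln_income": -0.058,
 "ex_smoker": 0.313,
 "smoker": -0.829,
 "drinker_over_limit": -0.134,
 "drinker_under_limit": -0.664,
 "diet_score": -0.024,
 "participation": -0.516,
 "duration_low_vigour": 0.101,
 "duration_moderate_vigour": -0.035,
 "duration_high_vigour": -0.075
}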