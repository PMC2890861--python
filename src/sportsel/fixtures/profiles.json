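{
 "profile_1": {
  "health_good": 0,
  "drinker_under_limit": 1,
  "wellbeing_good": 1,
  "drinker_over_limit": 0,
  "wellbeing_fair": 0,
  "wellbeing_missing": 0,
  "tv_hours_week": 5.822,
  "age_45_54": 0,
  "accident": 0,
  "age_35_44": 1,
  "age_16_24": 0,
  "inactive": 0,
  "n_children_under_2": 0,
  "n_children_2_15": 0,
  "smoker": 0,
  "car_available": 1,
  "health_fair": 0,
  "unemployed": 0,
  "age_25_34": 0,
  "area_bmi": 27.032,
  "diet_score": 18,
  "gender_male": 1,
  "illness_limiting": 0,
  "ex_smoker": 0,
  "ln_income": 10,
  "retired": 0,
  "no_education": 0,
  "mother_alive": 1,
  "divorced_sep_widowed": 0,
  "illness_non_limiting": 0,
  "area_sport_hours": 1.87,
  "health_very_good": 1,
  "single": 0
 },
 "profile_2": {
  "health_good": 1,
  "drinker_under_limit": 0,
  "wellbeing_good": 0,
  "drinker_over_limit": 0,
  "wellbeing_fair": 1,
  "wellbeing_missing": 0,
  "tv_hours_week": 5.822,
  "age_45_54": 0,
  "accident": 0,
  "age_35_44": 1,
  "age_16_24": 0,
  "inactive": 1,
  "n_children_under_2": 1,
  "n_children_2_15": 2,
  "smoker": 0,
  "car_available": 1,
  "health_fair": 0,
  "unemployed": 0,
  "age_25_34": 0,
  "area_bmi": 27.032,
  "diet_score": 18,
  "gender_male": 0,
  "illness_limiting": 0,
  "ex_smoker": 0,
  "ln_income": 10,
  "retired": 0,
  "no_education": 0,
  "mother_alive": 1,
  "divorced_sep_widowed": 0,
  "illness_non_limiting": 0,
  "area_sport_hours": 1.87,
  "health_very_good": 0,
  "single": 0
 },
 "profile_3": {
  "health_good": 0,
  "drinker_under_limit": 0,
  "wellbeing_good": 1,
  "drinker_over_limit": 1,
  "wellbeing_fair": 0,
  "wellbeing_missing": 0,
  "tv_hours_week": 5.822,
  "age_45_54": 0,
  "accident": 0,
  "age_35_44": 0,
  "age_16_24": 1,
  "inactive": 0,
  "n_children_under_2": 0,
  "n_children_2_15": 0,
  "smoker": 1,
  "car_available": 0,
  "health_fair": 0,
  "unemployed": 1,
  "age_25_34": 0,
  "area_bmi": 27.032,
  "diet_score": 14,
  "gender_male": 1,
  "illness_limiting": 0,
  "ex_smoker": 0,
  "ln_income": 9,
  "retired": 0,
  "no_education": 1,
  "mother_alive": 1,
  "divorced_sep_widowed": 0,
  "illness_non_limiting": 0,
  "area_sport_hours": 1.87,
  "health_very_good": 1,
  "single": 1
 }
}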