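{
 "n": 4380,
 "n1": 2327,
 "independence": {
  "loglik": -9298.29,
  "alpha": 0.315,
  "beta": {
   "constant": 3.338,
   "gender_male": 0.19,
   "age_16_24": 0.771,
   "age_25_34": 0.542,
   "age_35_44": 0.381,
   "age_45_54": 0.09,
   "ln_income": 0.11,
   "single": 0.222,
   "divorced_sep_widowed": 0.158,
   "n_children_2_15": 0.079,
   "n_children_under_2": -0.181,
   "mother_alive": 0.106,
   "tv_hours_week": -0.036,
   "car_available": 0.095,
   "no_education": -0.337,
   "retired": 0.289,
   "unemployed": 0.124,
   "inactive": -0.056,
   "health_very_good": 0.613,
   "health_good": 0.437,
   "health_fair": 0.233,
   "wellbeing_good": 0.022,
   "wellbeing_fair": 0.192,
   "wellbeing_missing": -0.236,
   "accident": 0.13,
   "area_sport_hours": 0.412,
   "area_bmi": -0.241,
   "smoker": -0.194,
   "ex_smoker": 0.101,
   "drinker_under_limit": 0.172,
   "drinker_over_limit": 0.183,
   "diet_score": 0.029
  },
  "gamma": {
   "constant": 1.493,
   "gender_male": 0.119,
   "age_16_24": 0.024,
   "age_25_34": 0.057,
   "age_35_44": 0.044,
   "age_45_54": 0.083,
   "single": 0.124,
   "divorced_sep_widowed": -0.154,
   "n_children_2_15": -0.039,
   "n_children_under_2": -0.226,
   "mother_alive": -0.005,
   "tv_hours_week": -0.008,
   "retired": -0.076,
   "unemployed": 0.05,
   "inactive": 0.003,
   "health_very_good": 0.381,
   "health_good": 0.328,
   "health_fair": 0.317,
   "illness_limiting": -0.088,
   "illness_non_limiting": 0.019,
   "smoker": -0.029,
   "ex_smoker": 0.044,
   "drinker_under_limit": 0.005,
   "drinker_over_limit": 0.018,
   "diet_score": -0.004,
   "vigour_moderate": -0.78,
   "vigour_high": -0.675
  }
 },
 "frank": {
  "loglik": -9155.25,
  "alpha": 0.218,
  "theta": 5.597,
  "kendall_tau": 0.492,
  "beta": {
   "constant": 3.277,
   "gender_male": 0.2,
   "age_16_24": 0.697,
   "age_25_34": 0.491,
   "age_35_44": 0.352,
   "age_45_54": 0.096,
   "ln_income": 0.107,
   "single": 0.238,
   "divorced_sep_widowed": 0.122,
   "n_children_2_15": 0.042,
   "n_children_under_2": -0.223,
   "mother_alive": 0.102,
   "tv_hours_week": -0.037,
   "car_available": 0.015,
   "no_education": -0.325,
   "retired": 0.234,
   "unemployed": 0.185,
   "inactive": -0.05,
   "health_very_good": 0.608,
   "health_good": 0.459,
   "health_fair": 0.24,
   "wellbeing_good": -0.009,
   "wellbeing_fair": 0.164,
   "wellbeing_missing": -0.252,
   "accident": 0.058,
   "area_sport_hours": 0.309,
   "area_bmi": -0.226,
   "smoker": -0.155,
   "ex_smoker": 0.094,
   "drinker_under_limit": 0.142,
   "drinker_over_limit": 0.15,
   "diet_score": 0.028
  },
  "gamma": {
   "constant": 1.325,
   "gender_male": 0.172,
   "age_16_24": 0.203,
   "age_25_34": 0.187,
   "age_35_44": 0.134,
   "age_45_54": 0.133,
   "single": 0.175,
   "divorced_sep_widowed": -0.116,
   "n_children_2_15": -0.029,
   "n_children_under_2": -0.285,
   "mother_alive": 0.038,
   "tv_hours_week": -0.019,
   "retired": -0.024,
   "unemployed": 0.073,
   "inactive": -0.04,
   "health_very_good": 0.55,
   "health_good": 0.433,
   "health_fair": 0.359,
   "illness_limiting": -0.098,
   "illness_non_limiting": 0.02,
   "smoker": -0.076,
   "ex_smoker": 0.066,
   "drinker_under_limit": 0.034,
   "drinker_over_limit": 0.046,
   "diet_score": 0.002,
   "vigour_moderate": -0.861,
   "vigour_high": -0.71
  }
 },
 "subsample_theta": {
  "women": 6.067,
  "men": 6.156
 }
}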