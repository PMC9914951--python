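{
 "description": "Reference coefficient set for the per-occasion drinking model: (i) number of mini episodes r = 1 + exp(linear predictor), (ii) probability of stopping p = logistic(linear predictor). Estimated on combined 2010-2011 US general-population survey microdata (past-30-day drinkers). Age reference band 20-25; gender reference male; K = usual drinks per drinking day, M = drinking days in past 30 days.",
 "r_terms": {
  "constant": {"estimate": 2.239, "ci_low": 2.000, "ci_high": 2.478},
  "age_12_14": {"estimate": -0.033, "ci_low": -0.126, "ci_high": 0.061},
  "age_15_17": {"estimate": 0.014, "ci_low": -0.017, "ci_high": 0.046},
  "age_18_19": {"estimate": 0.020, "ci_low": -0.009, "ci_high": 0.048},
  "age_26_29": {"estimate": -0.026, "ci_low": -0.061, "ci_high": 0.010},
  "age_30_34": {"estimate": -0.014, "ci_low": -0.050, "ci_high": 0.022},
  "age_35_49": {"estimate": -0.081, "ci_low": -0.109, "ci_high": -0.053},
  "age_50_64": {"estimate": -0.215, "ci_low": -0.265, "ci_high": -0.165},
  "age_65_plus": {"estimate": -0.423, "ci_low": -0.527, "ci_high": -0.319},
  "female": {"estimate": -0.079, "ci_low": -0.097, "ci_high": -0.060},
  "log_inv_k": {"estimate": -3.109, "ci_low": -3.269, "ci_high": -2.950},
  "log_inv_k_sq": {"estimate": -0.943, "ci_low": -1.005, "ci_high": -0.882},
  "log_m": {"estimate": -2.055, "ci_low": -2.273, "ci_high": -1.838},
  "log_m_sq": {"estimate": 0.368, "ci_low": 0.314, "ci_high": 0.423}
 },
 "p_terms": {
  "constant": {"estimate": 3.077, "ci_low": 2.871, "ci_high": 3.283},
  "log_inv_k": {"estimate": -0.964, "ci_low": -1.092, "ci_high": -0.836},
  "log_inv_k_sq": {"estimate": -0.563, "ci_low": -0.614, "ci_high": -0.512},
  "log_m": {"estimate": -1.925, "ci_low": -2.132, "ci_high": -1.719},
  "log_m_sq": {"estimate": 0.325, "ci_low": 0.274, "ci_high": 0.375}
 }
}
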