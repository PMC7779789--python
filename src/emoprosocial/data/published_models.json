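{
  "description": "Standardized coefficients of the six published moderation models (outcome: daily prosocial score; focal predictor: one emotion; moderator: daily newly confirmed cases), with the moderator's printed descriptive moments and observed minimum. b1 = emotion coefficient, b3 = emotion x severity product coefficient, both on the standardized scale. Inputs for desk-scale simple-slope replay.",
  "moderator": {
    "name": "new_cases",
    "mean": 1929.68,
    "sd": 2325.36,
    "min": 77.0,
    "n": 41
  },
  "models": {
    "happiness": {"b1": -0.09, "b2": 0.26, "b3": -0.27, "r2": 0.12},
    "anger":     {"b1": 0.45,  "b2": 0.79, "b3": 0.77,  "r2": 0.28},
    "sadness":   {"b1": -0.12, "b2": 0.70, "b3": -0.57, "r2": 0.25},
    "fear":      {"b1": -0.26, "b2": 0.24, "b3": 0.14,  "r2": 0.19},
    "disgust":   {"b1": -0.01, "b2": 0.42, "b3": 0.36,  "r2": 0.13},
    "surprise":  {"b1": -0.11, "b2": 0.91, "b3": -0.62, "r2": 0.33}
  }
}
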