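{
  "markers": ["afp", "free_bhcg", "ue3", "shla_g"],
  "group_sizes": {"control": 797, "T21": 139, "T18": 83},
  "groups": {
    "control": {
      "n": 797,
      "median_mom": [1.0, 1.0, 1.0, 1.0],
      "mean_log10_mom": [-0.0067, 0.0622, -0.0163, 0.0455],
      "sd_log10_mom": [0.16057, 0.39822, 0.16962, 0.22564],
      "correlation": [
        [1.0, -0.134, 0.525, -0.075],
        [-0.134, 1.0, -0.293, 0.095],
        [0.525, -0.293, 1.0, -0.052],
        [-0.075, 0.095, -0.052, 1.0]
      ]
    },
    "T21": {
      "n": 139,
      "median_mom": [0.7149, 2.5804, 0.7891, 1.18],
      "mean_log10_mom": [-0.1457, 0.3651, -0.139, 0.1014],
      "sd_log10_mom": [0.20747, 0.45804, 0.23251, 0.22433],
      "correlation": [
        [1.0, 0.167, 0.228, 0.003],
        [0.167, 1.0, -0.075, 0.291],
        [0.228, -0.075, 1.0, 0.164],
        [0.003, 0.291, 0.164, 1.0]
      ]
    },
    "T18": {
      "n": 83,
      "median_mom": [0.5401, 0.2219, 0.833, 0.45],
      "mean_log10_mom": [-0.1978, -0.6133, -0.3538, -0.3269],
      "sd_log10_mom": [0.25615, 0.52362, 0.28058, 0.21661],
      "correlation": [
        [1.0, 0.191, -0.054, -0.033],
        [0.191, 1.0, 0.233, -0.03],
        [-0.054, 0.233, 1.0, 0.212],
        [-0.033, -0.03, 0.212, 1.0]
      ]
    }
  },
  "control_medians": {
    "shla_g": 106.3,
    "afp": {"15": 30.0, "16": 34.5, "17": 39.7, "18": 45.6, "19": 52.5},
    "free_bhcg": {"15": 22.0, "16": 19.1, "17": 16.6, "18": 14.5, "19": 12.6},
    "ue3": {"15": 3.8, "16": 4.7, "17": 5.8, "18": 7.2, "19": 8.9}
  },
  "demographics": {
    "age_range": [18.0, 35.0],
    "weight_median_kg": 54.5,
    "weight_sigma_log10": 0.068,
    "gestational_weeks": [15, 16, 17, 18, 19]
  }
}
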