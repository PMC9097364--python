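{
  "comment": "Calibration constants for the synthetic generators. Claw curvature means (deg) and arc-ratio baselines per pedal-ecology label; jaw depth/length aspect distributions per diet label; mass ranges (g) per guild.",
  "pedal": {
    "Ground":     {"oo_mean": 40.0, "oo_sd": 8.0, "ratio_DI": 0.75, "ratio_DII": 1.05, "ratio_DIV": 0.85, "ratio_sd": 0.05},
    "Perch":      {"oo_mean": 95.0, "oo_sd": 8.0, "ratio_DI": 0.70, "ratio_DII": 0.80, "ratio_DIV": 0.80, "ratio_sd": 0.05},
    "Restraint":  {"oo_mean": 105.0, "oo_sd": 8.0, "ratio_DI": 1.10, "ratio_DII": 1.15, "ratio_DIV": 0.80, "ratio_sd": 0.05},
    "Strike":     {"oo_mean": 100.0, "oo_sd": 8.0, "ratio_DI": 1.05, "ratio_DII": 1.10, "ratio_DIV": 0.85, "ratio_sd": 0.05},
    "Suffocate":  {"oo_mean": 90.0, "oo_sd": 8.0, "ratio_DI": 0.95, "ratio_DII": 0.95, "ratio_DIV": 0.95, "ratio_sd": 0.05},
    "Pierce":     {"oo_mean": 110.0, "oo_sd": 6.0, "ratio_DI": 1.00, "ratio_DII": 1.00, "ratio_DIV": 1.00, "ratio_sd": 0.05},
    "Scavenger":  {"oo_mean": 70.0, "oo_sd": 8.0, "ratio_DI": 0.85, "ratio_DII": 0.90, "ratio_DIV": 0.90, "ratio_sd": 0.05}
  },
  "jaw": {
    "strong": {"aspect_mean": 0.32, "aspect_sd": 0.025, "length_mm": [20.0, 60.0]},
    "weak":   {"aspect_mean": 0.075, "aspect_sd": 0.008, "length_mm": [20.0, 80.0]},
    "strong_guilds": ["GranivoreH", "GranivoreS", "Folivore", "FrugivoreH", "FrugivoreS", "Nectarivore", "Scavenger"],
    "weak_guilds": ["Generalist", "InvertivoreH", "InvertivoreM", "InvertivoreS", "Piscivore", "TetrapodHunter"]
  },
  "mass_g": {
    "invertivore": [6.0, 300.0],
    "vertivore": [450.0, 9625.0],
    "grannect": [5.0, 250.0],
    "folfrug": [400.0, 4400.0],
    "generalist": [7.0, 8786.0]
  }
}
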