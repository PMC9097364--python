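{
  "comment": "Percentage-of-diet thresholds per diet category. 'standard' and 'semi' are inclusive (>=) minimum percentages of the named column after preprocessing. Generalist uses a maximum over all columns instead.",
  "inclusive": true,
  "categories": {
    "Folivore":       {"column": "PlantO", "standard": 80, "semi": 60},
    "Frugivore":      {"column": "Fruit",  "standard": 80, "semi": 60},
    "Granivore":      {"column": "Seed",   "standard": 90, "semi": 70},
    "Invertivore":    {"column": "Inv",    "standard": 90, "semi": 60},
    "Nectarivore":    {"column": "Nect",   "standard": 80, "semi": 60},
    "Piscivore":      {"column": "Fish",   "standard": 70, "semi": 50},
    "Scavenger":      {"column": "Scav",   "standard": 100, "semi": 50},
    "TetrapodHunter": {"column": "Tetr",   "standard": 80, "semi": 60}
  },
  "generalist": {"standard_max": 30, "semi_max": 40},
  "rollups": {
    "Carnivore": ["InvertivoreH", "InvertivoreM", "InvertivoreS", "Piscivore", "Scavenger", "TetrapodHunter"],
    "Herbivore": ["Folivore", "FrugivoreH", "FrugivoreS", "GranivoreH", "GranivoreS", "Nectarivore"],
    "Omnivore": ["Generalist"]
  }
}
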