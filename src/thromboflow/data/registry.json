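{
  "schema_version": 1,
  "surfaces": {
    "M1": {
      "id": "M1",
      "description": "BSA control (blocking buffer)",
      "components": [{"name": "BSA", "concentration": 1.0, "unit": "%"}],
      "receptors": [],
      "co_coating": "TF",
      "co_coating_dose": 500.0,
      "co_coating_dose_unit": "pM",
      "co_coating_optional": true,
      "tf_in_medium": false
    },
    "M2": {
      "id": "M2",
      "description": "rhodocytin + VWF",
      "components": [
        {"name": "rhodocytin", "concentration": 250.0, "unit": "ug/mL"},
        {"name": "VWF", "concentration": 50.0, "unit": "ug/mL"}
      ],
      "receptors": ["GPIb", "CLEC2"],
      "co_coating": "TF",
      "co_coating_dose": 500.0,
      "co_coating_dose_unit": "pM",
      "co_coating_optional": true,
      "tf_in_medium": false
    },
    "M3": {
      "id": "M3",
      "description": "laminin + VWF",
      "components": [
        {"name": "laminin", "concentration": 100.0, "unit": "ug/mL"},
        {"name": "VWF", "concentration": 50.0, "unit": "ug/mL"}
      ],
      "receptors": ["GPIb", "a6b1"],
      "co_coating": "TF",
      "co_coating_dose": 500.0,
      "co_coating_dose_unit": "pM",
      "co_coating_optional": true,
      "tf_in_medium": false
    },
    "M4": {
      "id": "M4",
      "description": "collagen-III (binds plasma VWF)",
      "components": [{"name": "collagen-III", "concentration": 100.0, "unit": "ug/mL"}],
      "receptors": ["GPIb", "GPVI", "a2b1"],
      "co_coating": "TF",
      "co_coating_dose": 500.0,
      "co_coating_dose_unit": "pM",
      "co_coating_optional": true,
      "tf_in_medium": false
    },
    "M5": {
      "id": "M5",
      "description": "collagen-I low density (binds plasma VWF)",
      "components": [{"name": "collagen-I", "concentration": 10.0, "unit": "ug/mL"}],
      "receptors": ["GPIb", "GPVI", "a2b1"],
      "co_coating": "TF",
      "co_coating_dose": 500.0,
      "co_coating_dose_unit": "pM",
      "co_coating_optional": true,
      "tf_in_medium": false
    },
    "M6": {
      "id": "M6",
      "description": "collagen-I high density (binds plasma VWF)",
      "components": [{"name": "collagen-I", "concentration": 50.0, "unit": "ug/mL"}],
      "receptors": ["GPIb", "GPVI", "a2b1"],
      "co_coating": "TF",
      "co_coating_dose": 500.0,
      "co_coating_dose_unit": "pM",
      "co_coating_optional": true,
      "tf_in_medium": false
    },
    "M7": {
      "id": "M7",
      "description": "GFOGER-(GPO)n + VWF-binding peptide",
      "components": [
        {"name": "GFOGER-GPO", "concentration": 250.0, "unit": "ug/mL"},
        {"name": "VWF-BP", "concentration": 100.0, "unit": "ug/mL"}
      ],
      "receptors": ["GPIb", "GPVI", "a2b1"],
      "co_coating": "TF",
      "co_coating_dose": 500.0,
      "co_coating_dose_unit": "pM",
      "co_coating_optional": true,
      "tf_in_medium": false
    },
    "M8": {
      "id": "M8",
      "description": "collagen-I high density + thrombomodulin; TF in medium",
      "components": [{"name": "collagen-I", "concentration": 50.0, "unit": "ug/mL"}],
      "receptors": ["GPIb", "GPVI", "a2b1"],
      "co_coating": "TM",
      "co_coating_dose": 10.0,
      "co_coating_dose_unit": "nM",
      "co_coating_optional": false,
      "tf_in_medium": true
    },
    "M9": {
      "id": "M9",
      "description": "collagen-I high density + activated protein C; TF in medium",
      "components": [{"name": "collagen-I", "concentration": 50.0, "unit": "ug/mL"}],
      "receptors": ["GPIb", "GPVI", "a2b1"],
      "co_coating": "APC",
      "co_coating_dose": 10.0,
      "co_coating_dose_unit": "nM",
      "co_coating_optional": false,
      "tf_in_medium": true
    }
  },
  "parameters": {
    "P1": {
      "id": "P1",
      "description": "Platelet adhesion (DiOC6)",
      "channel": "platelet",
      "unit": "%SAC",
      "range": [0.0, 100.0],
      "integer": false,
      "capture_times": [0, 2, 4, 6, 8]
    },
    "P2": {
      "id": "P2",
      "description": "Platelet phosphatidylserine exposure (annexin A5)",
      "channel": "ps",
      "unit": "%SAC",
      "range": [0.0, 100.0],
      "integer": false,
      "capture_times": [0, 2, 4, 6, 8]
    },
    "P3": {
      "id": "P3",
      "description": "Thrombus coverage (bright-field)",
      "channel": "brightfield",
      "unit": "%SAC",
      "range": [0.0, 100.0],
      "integer": false,
      "capture_times": [0, 2, 4, 6, 8]
    },
    "P4": {
      "id": "P4",
      "description": "Thrombus morphology score",
      "channel": "brightfield",
      "unit": "score",
      "range": [0, 5],
      "integer": true,
      "capture_times": [0, 2, 4, 6, 8]
    },
    "P5": {
      "id": "P5",
      "description": "Thrombus aggregation score",
      "channel": "brightfield",
      "unit": "score",
      "range": [0, 3],
      "integer": true,
      "capture_times": [0, 2, 4, 6, 8]
    },
    "P6": {
      "id": "P6",
      "description": "Thrombus contraction score",
      "channel": "brightfield",
      "unit": "score",
      "range": [0, 3],
      "integer": true,
      "capture_times": [0, 2, 4, 6, 8]
    },
    "P7": {
      "id": "P7",
      "description": "Fibrin deposition (labelled fibrin(ogen))",
      "channel": "fibrin",
      "unit": "%SAC",
      "range": [0.0, 100.0],
      "integer": false,
      "capture_times": [0, 2, 4, 6, 8]
    },
    "P8": {
      "id": "P8",
      "description": "Fibrin score",
      "channel": "brightfield",
      "unit": "score",
      "range": [0, 3],
      "integer": true,
      "capture_times": [0, 2, 4, 6, 8]
    },
    "P9": {
      "id": "P9",
      "description": "Shorter time to fibrin (11 - t)",
      "channel": "fibrin",
      "unit": "11 - t min",
      "range": [0.0, 11.0],
      "integer": false,
      "capture_times": [0, 2, 4, 6, 8, 10]
    }
  }
}
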