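{
  "comment": [
    "Default linguistic variables. Set counts per variable are (2,4,3,3,4,6,4,2),",
    "whose product is the full 13,824-rule Cartesian grid. Waiting time carries",
    "6 sets (it is the only uncapped, linearly-scored continuous factor and needs",
    "the most linguistic resolution); HLA mismatch carries 4 (integer-valued and",
    "effectively crisp). Plateaus are placed where cohort data mass and the",
    "scoring bin boundaries lie; ramps extend 2.5x the inter-plateau gap so that",
    "tree-extracted rules keep firing across their whole source interval."
  ],
  "inputs": [
    {
      "name": "medical_urgency",
      "universe": [0, 1],
      "sets": [
        {"name": "non_urgent", "a": 0, "b": 0, "c": 0.2, "d": 0.8},
        {"name": "urgent", "a": 0.2, "b": 0.8, "c": 1, "d": 1}
      ]
    },
    {
      "name": "pra",
      "universe": [0, 100],
      "sets": [
        {"name": "unsensitized", "a": 0, "b": 0, "c": 30, "d": 67.5},
        {"name": "low", "a": 7.5, "b": 45, "c": 60, "d": 72.5},
        {"name": "medium", "a": 52.5, "b": 65, "c": 75, "d": 92.5},
        {"name": "high", "a": 64.5, "b": 82, "c": 100, "d": 100}
      ]
    },
    {
      "name": "recipient_age",
      "universe": [0, 80],
      "sets": [
        {"name": "pediatric", "a": 0, "b": 0, "c": 12, "d": 27},
        {"name": "adult", "a": 3, "b": 18, "c": 50, "d": 75},
        {"name": "senior", "a": 35, "b": 60, "c": 80, "d": 80}
      ]
    },
    {
      "name": "age_difference",
      "universe": [0, 60],
      "sets": [
        {"name": "small", "a": 0, "b": 0, "c": 4, "d": 9},
        {"name": "moderate", "a": 1, "b": 6, "c": 13, "d": 23},
        {"name": "large", "a": 7, "b": 17, "c": 60, "d": 60}
      ]
    },
    {
      "name": "hla_mismatch",
      "universe": [0, 5],
      "sets": [
        {"name": "mm01", "a": 0, "b": 0, "c": 1, "d": 3.5},
        {"name": "mm23", "a": 0, "b": 2, "c": 3, "d": 5},
        {"name": "mm4", "a": 1.5, "b": 4, "c": 4, "d": 5},
        {"name": "mm5", "a": 2.5, "b": 5, "c": 5, "d": 5}
      ]
    },
    {
      "name": "waiting_time",
      "universe": [0, 10],
      "sets": [
        {"name": "minimal", "a": 0, "b": 0, "c": 0.5, "d": 1.75},
        {"name": "very_short", "a": 0, "b": 1, "c": 1.6, "d": 2.85},
        {"name": "short", "a": 0.85, "b": 2.1, "c": 2.8, "d": 4.3},
        {"name": "moderate", "a": 1.9, "b": 3.4, "c": 4.4, "d": 6.4},
        {"name": "long", "a": 3.2, "b": 5.2, "c": 6.5, "d": 10},
        {"name": "very_long", "a": 4.25, "b": 8, "c": 10, "d": 10}
      ]
    },
    {
      "name": "predicted_survival",
      "universe": [0, 20],
      "sets": [
        {"name": "poor", "a": 0, "b": 0, "c": 1.5, "d": 5.25},
        {"name": "fair", "a": 0, "b": 3, "c": 5, "d": 7.5},
        {"name": "good", "a": 3.5, "b": 6, "c": 9, "d": 14},
        {"name": "excellent", "a": 6, "b": 11, "c": 20, "d": 20}
      ]
    },
    {
      "name": "abo_identical",
      "universe": [0, 1],
      "sets": [
        {"name": "compatible", "a": 0, "b": 0, "c": 0.2, "d": 0.8},
        {"name": "identical", "a": 0.2, "b": 0.8, "c": 1, "d": 1}
      ]
    }
  ],
  "output": {
    "name": "priority",
    "universe": [0, 100],
    "sets": [
      {"name": "very_low", "a": 0, "b": 0, "c": 10, "d": 30},
      {"name": "low", "a": 10, "b": 30, "c": 30, "d": 50},
      {"name": "medium", "a": 30, "b": 50, "c": 50, "d": 70},
      {"name": "high", "a": 50, "b": 70, "c": 70, "d": 90},
      {"name": "very_high", "a": 70, "b": 90, "c": 100, "d": 100}
    ]
  }
}
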