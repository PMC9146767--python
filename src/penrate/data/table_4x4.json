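{
  "array": "4x4",
  "n": 4,
  "note": "Reference current-interval calibration for the 4x4 sheet microneedle array, transcribed verbatim from the device study's printed interval division (distance 1 = I_AB, 2 = I_AC, 3 = I_AD). Printed values preserved as-is, including the distance-2 interval 5 upper bound printed as 394 uA (inconsistent with the adjacent 294 uA boundary).",
  "distances": {
    "1": [
      {"interval": 1, "label": "0-0", "current_low": 484, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1", "current_low": 426, "current_high": 484, "interval_length": 57},
      {"interval": 3, "label": "1-1", "current_low": 382, "current_high": 426, "interval_length": 44},
      {"interval": 4, "label": "0-2", "current_low": 346, "current_high": 382, "interval_length": 36},
      {"interval": 5, "label": "1-2", "current_low": 304, "current_high": 346, "interval_length": 42},
      {"interval": 6, "label": "2-2", "current_low": 256, "current_high": 304, "interval_length": 48},
      {"interval": 7, "label": "0-3", "current_low": 226, "current_high": 256, "interval_length": 30},
      {"interval": 8, "label": "1-3", "current_low": 207, "current_high": 226, "interval_length": 19},
      {"interval": 9, "label": "2-3", "current_low": 172, "current_high": 207, "interval_length": 34},
      {"interval": 10, "label": "3-3", "current_low": 88, "current_high": 172, "interval_length": 84},
      {"interval": 11, "label": "4+", "current_low": 0, "current_high": 88, "interval_length": 88}
    ],
    "2": [
      {"interval": 1, "label": "0-0", "current_low": 387, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1", "current_low": 349, "current_high": 387, "interval_length": 37},
      {"interval": 3, "label": "1-1", "current_low": 319, "current_high": 349, "interval_length": 30},
      {"interval": 4, "label": "0-2", "current_low": 294, "current_high": 319, "interval_length": 25},
      {"interval": 5, "label": "1-2", "current_low": 263, "current_high": 394, "interval_length": 31},
      {"interval": 6, "label": "2-2", "current_low": 226, "current_high": 263, "interval_length": 37},
      {"interval": 7, "label": "0-3", "current_low": 203, "current_high": 226, "interval_length": 24},
      {"interval": 8, "label": "1-3", "current_low": 187, "current_high": 203, "interval_length": 15},
      {"interval": 9, "label": "2-3", "current_low": 159, "current_high": 187, "interval_length": 29},
      {"interval": 10, "label": "3-3", "current_low": 83, "current_high": 159, "interval_length": 76},
      {"interval": 11, "label": "4+", "current_low": 0, "current_high": 83, "interval_length": 83}
    ],
    "3": [
      {"interval": 1, "label": "0-0", "current_low": 341, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1", "current_low": 311, "current_high": 341, "interval_length": 30},
      {"interval": 3, "label": "1-1", "current_low": 287, "current_high": 311, "interval_length": 24},
      {"interval": 4, "label": "0-2", "current_low": 266, "current_high": 287, "interval_length": 21},
      {"interval": 5, "label": "1-2", "current_low": 240, "current_high": 266, "interval_length": 26},
      {"interval": 6, "label": "2-2", "current_low": 209, "current_high": 240, "interval_length": 31},
      {"interval": 7, "label": "0-3", "current_low": 189, "current_high": 209, "interval_length": 20},
      {"interval": 8, "label": "1-3", "current_low": 176, "current_high": 189, "interval_length": 13},
      {"interval": 9, "label": "2-3", "current_low": 150, "current_high": 176, "interval_length": 26},
      {"interval": 10, "label": "3-3", "current_low": 80, "current_high": 150, "interval_length": 70},
      {"interval": 11, "label": "4+", "current_low": 0, "current_high": 80, "interval_length": 80}
    ]
  }
}
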