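{
  "array": "3x3",
  "n": 3,
  "note": "Reference current-interval calibration for the 3x3 sheet microneedle array, transcribed verbatim from the device study's printed interval division (one block per tested pair distance; distance 1 = adjacent sheets, I_AB; distance 2 = I_AC). Printed values are preserved as-is, including the interval 5/6 overlap (171-204 vs 83-177 uA) and interval-length entries that disagree with the printed bounds.",
  "distances": {
    "1": [
      {"interval": 1, "label": "0-0", "current_low": 360, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1", "current_low": 301, "current_high": 360, "interval_length": 59},
      {"interval": 3, "label": "1-1", "current_low": 246, "current_high": 301, "interval_length": 55},
      {"interval": 4, "label": "0-2", "current_low": 204, "current_high": 246, "interval_length": 42},
      {"interval": 5, "label": "1-2", "current_low": 171, "current_high": 204, "interval_length": 34},
      {"interval": 6, "label": "2-2", "current_low": 83, "current_high": 177, "interval_length": 87},
      {"interval": 7, "label": "3+", "current_low": 0, "current_high": 83, "interval_length": 65}
    ],
    "2": [
      {"interval": 1, "label": "0-0", "current_low": 289, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1", "current_low": 250, "current_high": 289, "interval_length": 39},
      {"interval": 3, "label": "1-1", "current_low": 210, "current_high": 250, "interval_length": 39},
      {"interval": 4, "label": "0-2", "current_low": 179, "current_high": 210, "interval_length": 31},
      {"interval": 5, "label": "1-2", "current_low": 152, "current_high": 179, "interval_length": 27},
      {"interval": 6, "label": "2-2", "current_low": 76, "current_high": 152, "interval_length": 76},
      {"interval": 7, "label": "3+", "current_low": 0, "current_high": 76, "interval_length": 58}
    ]
  }
}
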