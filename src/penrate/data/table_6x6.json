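{
  "array": "6x6",
  "n": 6,
  "note": "Reference current-interval calibration for the 6x6 sheet microneedle array, transcribed verbatim from the device study's printed interval division (distance 1 = I_AB through distance 5 = I_AF). For six-tip sheets single states are no longer separable by current, so each interval maps to a printed group of states; the grouping reflects the study's forward-model current clustering and is packaged as-is rather than re-derived.",
  "distances": {
    "1": [
      {"interval": 1, "label": "0-0", "current_low": 725, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1, 1-1", "current_low": 633, "current_high": 725, "interval_length": 91},
      {"interval": 3, "label": "0-2, 1-2", "current_low": 556, "current_high": 633, "interval_length": 77},
      {"interval": 4, "label": "0-3, 2-2, 1-3, 2-3", "current_low": 436, "current_high": 556, "interval_length": 118},
      {"interval": 5, "label": "0-4, 3-3, 1-4, 2-4, 3-4, 4-4", "current_low": 270, "current_high": 436, "interval_length": 166},
      {"interval": 6, "label": "0-5, 1-5, 2-5, 3-5, 4-5, 5-5", "current_low": 95, "current_high": 270, "interval_length": 174},
      {"interval": 7, "label": "6+", "current_low": 0, "current_high": 95, "interval_length": 95}
    ],
    "2": [
      {"interval": 1, "label": "0-0", "current_low": 562, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1, 1-1", "current_low": 506, "current_high": 562, "interval_length": 56},
      {"interval": 3, "label": "0-2, 1-2", "current_low": 455, "current_high": 506, "interval_length": 50},
      {"interval": 4, "label": "0-3, 2-2, 1-3, 2-3", "current_low": 373, "current_high": 455, "interval_length": 82},
      {"interval": 5, "label": "0-4, 3-3, 1-4, 2-4, 3-4, 4-4", "current_low": 245, "current_high": 373, "interval_length": 127},
      {"interval": 6, "label": "0-5, 1-5, 2-5, 3-5, 4-5, 5-5", "current_low": 92, "current_high": 245, "interval_length": 152},
      {"interval": 7, "label": "6+", "current_low": 0, "current_high": 92, "interval_length": 91}
    ],
    "3": [
      {"interval": 1, "label": "0-0", "current_low": 486, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1, 1-1", "current_low": 443, "current_high": 486, "interval_length": 42},
      {"interval": 3, "label": "0-2, 1-2", "current_low": 403, "current_high": 443, "interval_length": 39},
      {"interval": 4, "label": "0-3, 2-2, 1-3, 2-3", "current_low": 337, "current_high": 403, "interval_length": 66},
      {"interval": 5, "label": "0-4, 3-3, 1-4, 2-4, 3-4, 4-4", "current_low": 229, "current_high": 337, "interval_length": 108},
      {"interval": 6, "label": "0-5, 1-5, 2-5, 3-5, 4-5, 5-5", "current_low": 89, "current_high": 229, "interval_length": 140},
      {"interval": 7, "label": "6+", "current_low": 0, "current_high": 89, "interval_length": 88}
    ],
    "4": [
      {"interval": 1, "label": "0-0", "current_low": 436, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1, 1-1", "current_low": 401, "current_high": 436, "interval_length": 34},
      {"interval": 3, "label": "0-2, 1-2", "current_low": 369, "current_high": 401, "interval_length": 32},
      {"interval": 4, "label": "0-3, 2-2, 1-3, 2-3", "current_low": 312, "current_high": 369, "interval_length": 56},
      {"interval": 5, "label": "0-4, 3-3, 1-4, 2-4, 3-4, 4-4", "current_low": 217, "current_high": 312, "interval_length": 95},
      {"interval": 6, "label": "0-5, 1-5, 2-5, 3-5, 4-5, 5-5", "current_low": 86, "current_high": 217, "interval_length": 130},
      {"interval": 7, "label": "6+", "current_low": 0, "current_high": 86, "interval_length": 86}
    ],
    "5": [
      {"interval": 1, "label": "0-0", "current_low": 397, "current_high": null, "interval_length": null},
      {"interval": 2, "label": "0-1, 1-1", "current_low": 368, "current_high": 397, "interval_length": 29},
      {"interval": 3, "label": "0-2, 1-2", "current_low": 340, "current_high": 368, "interval_length": 28},
      {"interval": 4, "label": "0-3, 2-2, 1-3, 2-3", "current_low": 291, "current_high": 340, "interval_length": 49},
      {"interval": 5, "label": "0-4, 3-3, 1-4, 2-4, 3-4, 4-4", "current_low": 206, "current_high": 291, "interval_length": 85},
      {"interval": 6, "label": "0-5, 1-5, 2-5, 3-5, 4-5, 5-5", "current_low": 84, "current_high": 206, "interval_length": 122},
      {"interval": 7, "label": "6+", "current_low": 0, "current_high": 84, "interval_length": 84}
    ]
  }
}
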