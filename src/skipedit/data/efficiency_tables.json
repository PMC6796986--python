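{
  "_note": "Editable default position-dependent editing-efficiency tables. Positions are 1-based protospacer positions with position 1 PAM-distal. 'relative' values are relative activities per position; they are multiplied by 'max_efficiency' (percent) to give the predicted editing efficiency of a target base at that position. The ABE values approximate the published ABE7.8 per-position activity profile (window 4-9); the BE3 values approximate the cytidine-deaminase window (4-8) used in the original CRISPR-SKIP design tool. Both are estimates digitized from figures rather than printed tables, and users with better calibration data should override this file.",
  "ABE": {
    "max_efficiency": 52.0,
    "relative": {"4": 0.25, "5": 0.85, "6": 1.0, "7": 0.9, "8": 0.55, "9": 0.3}
  },
  "BE3": {
    "max_efficiency": 50.0,
    "relative": {"4": 0.6, "5": 1.0, "6": 0.9, "7": 0.65, "8": 0.35}
  }
}
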