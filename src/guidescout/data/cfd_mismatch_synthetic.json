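{
 "mismatch": {
  "rU:dG": [
   1.0,
   0.95,
   0.9,
   0.85,
   0.85,
   0.85,
   0.8,
   0.75,
   0.7,
   0.65,
   0.6,
   0.55,
   0.5,
   0.4,
   0.35,
   0.3,
   0.25,
   0.25,
   0.3,
   0.35
  ],
  "rG:dT": [
   1.0,
   0.95,
   0.9,
   0.85,
   0.85,
   0.85,
   0.8,
   0.75,
   0.7,
   0.65,
   0.6,
   0.55,
   0.5,
   0.4,
   0.35,
   0.3,
   0.25,
   0.25,
   0.3,
   0.35
  ],
  "rC:dA": [
   0.8,
   0.76,
   0.72,
   0.68,
   0.68,
   0.68,
   0.64,
   0.6,
   0.56,
   0.52,
   0.48,
   0.44,
   0.4,
   0.32,
   0.28,
   0.24,
   0.2,
   0.2,
   0.24,
   0.28
  ],
  "rA:dA": [
   0.8,
   0.76,
   0.72,
   0.68,
   0.68,
   0.68,
   0.64,
   0.6,
   0.56,
   0.52,
   0.48,
   0.44,
   0.4,
   0.32,
   0.28,
   0.24,
   0.2,
   0.2,
   0.24,
   0.28
  ],
  "rU:dT": [
   0.75,
   0.712,
   0.675,
   0.637,
   0.637,
   0.637,
   0.6,
   0.562,
   0.525,
   0.488,
   0.45,
   0.413,
   0.375,
   0.3,
   0.262,
   0.225,
   0.188,
   0.188,
   0.225,
   0.262
  ],
  "rA:dG": [
   0.7,
   0.665,
   0.63,
   0.595,
   0.595,
   0.595,
   0.56,
   0.525,
   0.49,
   0.455,
   0.42,
   0.385,
   0.35,
   0.28,
   0.245,
   0.21,
   0.175,
   0.175,
   0.21,
   0.245
  ],
  "rG:dA": [
   0.7,
   0.665,
   0.63,
   0.595,
   0.595,
   0.595,
   0.56,
   0.525,
   0.49,
   0.455,
   0.42,
   0.385,
   0.35,
   0.28,
   0.245,
   0.21,
   0.175,
   0.175,
   0.21,
   0.245
  ],
  "rA:dC": [
   0.65,
   0.617,
   0.585,
   0.552,
   0.552,
   0.552,
   0.52,
   0.488,
   0.455,
   0.423,
   0.39,
   0.358,
   0.325,
   0.26,
   0.227,
   0.195,
   0.163,
   0.163,
   0.195,
   0.227
  ],
  "rU:dC": [
   0.6,
   0.57,
   0.54,
   0.51,
   0.51,
   0.51,
   0.48,
   0.45,
   0.42,
   0.39,
   0.36,
   0.33,
   0.3,
   0.24,
   0.21,
   0.18,
   0.15,
   0.15,
   0.18,
   0.21
  ],
  "rC:dT": [
   0.6,
   0.57,
   0.54,
   0.51,
   0.51,
   0.51,
   0.48,
   0.45,
   0.42,
   0.39,
   0.36,
   0.33,
   0.3,
   0.24,
   0.21,
   0.18,
   0.15,
   0.15,
   0.18,
   0.21
  ],
  "rG:dG": [
   0.45,
   0.427,
   0.405,
   0.383,
   0.383,
   0.383,
   0.36,
   0.338,
   0.315,
   0.293,
   0.27,
   0.248,
   0.225,
   0.18,
   0.158,
   0.135,
   0.113,
   0.113,
   0.135,
   0.158
  ],
  "rC:dC": [
   0.4,
   0.38,
   0.36,
   0.34,
   0.34,
   0.34,
   0.32,
   0.3,
   0.28,
   0.26,
   0.24,
   0.22,
   0.2,
   0.16,
   0.14,
   0.12,
   0.1,
   0.1,
   0.12,
   0.14
  ]
 }
}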