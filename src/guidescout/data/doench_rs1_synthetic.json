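{
 "intercept": 0.59763615,
 "gc_low": -0.2026259,
 "gc_high": -0.1665878,
 "weights": [
  [
   1,
   "G",
   -0.2753771
  ],
  [
   2,
   "A",
   -0.3238875
  ],
  [
   2,
   "C",
   0.17212887
  ],
  [
   3,
   "C",
   -0.1006662
  ],
  [
   4,
   "C",
   -0.2018029
  ],
  [
   4,
   "G",
   0.24595663
  ],
  [
   5,
   "A",
   0.03644004
  ],
  [
   5,
   "C",
   0.09837684
  ],
  [
   6,
   "C",
   -0.7411813
  ],
  [
   6,
   "G",
   -0.3932644
  ],
  [
   11,
   "A",
   -0.466099
  ],
  [
   14,
   "A",
   0.08537695
  ],
  [
   14,
   "C",
   -0.013814
  ],
  [
   15,
   "A",
   0.27262051
  ],
  [
   15,
   "C",
   -0.1190226
  ],
  [
   15,
   "T",
   -0.2859442
  ],
  [
   16,
   "A",
   0.09745459
  ],
  [
   16,
   "G",
   -0.1755462
  ],
  [
   17,
   "C",
   -0.3457955
  ],
  [
   17,
   "G",
   -0.6780964
  ],
  [
   18,
   "A",
   0.22508903
  ],
  [
   18,
   "C",
   -0.5077941
  ],
  [
   19,
   "G",
   -0.4173736
  ],
  [
   19,
   "T",
   -0.054307
  ],
  [
   20,
   "G",
   0.39907075
  ],
  [
   20,
   "T",
   -0.0907126
  ],
  [
   21,
   "C",
   0.06527781
  ],
  [
   21,
   "T",
   0.02827867
  ],
  [
   22,
   "T",
   -0.221352
  ],
  [
   23,
   "C",
   -0.1212962
  ],
  [
   23,
   "G",
   0.19977837
  ],
  [
   23,
   "T",
   -0.6890167
  ],
  [
   24,
   "A",
   0.03320673
  ],
  [
   24,
   "C",
   0.56603826
  ],
  [
   24,
   "G",
   0.61416615
  ],
  [
   26,
   "G",
   -0.7473647
  ],
  [
   27,
   "A",
   -0.3038915
  ],
  [
   28,
   "C",
   0.85619
  ],
  [
   29,
   "G",
   -0.4908167
  ]
 ]
}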