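[
  {"index": 1,  "nt_length": null, "aa_length": null, "region": "UTR5",    "splice_class": "constitutive"},
  {"index": 2,  "nt_length": 33,   "aa_length": 11,   "region": "ProAla",  "splice_class": "cassette"},
  {"index": 3,  "nt_length": 39,   "aa_length": 13,   "region": "ProAla",  "splice_class": "cassette"},
  {"index": 4,  "nt_length": 36,   "aa_length": 12,   "region": "ProAla",  "splice_class": "cassette"},
  {"index": 5,  "nt_length": 33,   "aa_length": 11,   "region": "ProAla",  "splice_class": "cassette"},
  {"index": 6,  "nt_length": null, "aa_length": null, "region": "C1",      "splice_class": "constitutive"},
  {"index": 7,  "nt_length": null, "aa_length": null, "region": "C1",      "splice_class": "constitutive"},
  {"index": 8,  "nt_length": null, "aa_length": null, "region": "M-motif", "splice_class": "constitutive"},
  {"index": 9,  "nt_length": null, "aa_length": null, "region": "M-motif", "splice_class": "constitutive"},
  {"index": 10, "nt_length": 54,   "aa_length": 18,   "region": "M-motif", "splice_class": "cassette"},
  {"index": 11, "nt_length": null, "aa_length": null, "region": "M-motif", "splice_class": "constitutive"},
  {"index": 12, "nt_length": null, "aa_length": null, "region": "C2",      "splice_class": "constitutive"},
  {"index": 13, "nt_length": null, "aa_length": null, "region": "C2",      "splice_class": "constitutive"},
  {"index": 14, "nt_length": null, "aa_length": null, "region": "C3",      "splice_class": "constitutive"},
  {"index": 15, "nt_length": null, "aa_length": null, "region": "C3",      "splice_class": "constitutive"},
  {"index": 16, "nt_length": null, "aa_length": null, "region": "C4",      "splice_class": "constitutive"},
  {"index": 17, "nt_length": null, "aa_length": null, "region": "C4",      "splice_class": "constitutive"},
  {"index": 18, "nt_length": null, "aa_length": null, "region": "C5",      "splice_class": "constitutive"},
  {"index": 19, "nt_length": null, "aa_length": null, "region": "C5",      "splice_class": "constitutive"},
  {"index": 20, "nt_length": null, "aa_length": null, "region": "C6",      "splice_class": "constitutive"},
  {"index": 21, "nt_length": null, "aa_length": null, "region": "C6",      "splice_class": "constitutive"},
  {"index": 22, "nt_length": null, "aa_length": null, "region": "C7",      "splice_class": "constitutive"},
  {"index": 23, "nt_length": 57,   "aa_length": 19,   "region": "C7",      "splice_class": "cassette"},
  {"index": 24, "nt_length": null, "aa_length": null, "region": "C7",      "splice_class": "constitutive"},
  {"index": 25, "nt_length": null, "aa_length": null, "region": "C8",      "splice_class": "constitutive"},
  {"index": 26, "nt_length": null, "aa_length": null, "region": "C8",      "splice_class": "constitutive"},
  {"index": 27, "nt_length": null, "aa_length": null, "region": "C9",      "splice_class": "constitutive"},
  {"index": 28, "nt_length": null, "aa_length": null, "region": "C9",      "splice_class": "constitutive"},
  {"index": 29, "nt_length": null, "aa_length": null, "region": "C10",     "splice_class": "constitutive"},
  {"index": 30, "nt_length": null, "aa_length": null, "region": "C10",     "splice_class": "constitutive"},
  {"index": 31, "nt_length": 57,   "aa_length": 19,   "region": "tail",    "splice_class": "alternate_terminal"},
  {"index": 32, "nt_length": null, "aa_length": null, "region": "tail",    "splice_class": "alternate_terminal"},
  {"index": 33, "nt_length": null, "aa_length": null, "region": "UTR3",    "splice_class": "alternate_terminal"}
]
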