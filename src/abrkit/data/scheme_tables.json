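{
  "version": "abrkit-tables-1",
  "comment": "CDR boundary labels per numbering scheme (inclusive, scheme collation) and the anchor position at which insertion letters are placed in each region.",
  "boundaries": {
    "kabat": {
      "light": {"L1": ["24", "34"], "L2": ["50", "56"], "L3": ["89", "97"]},
      "heavy": {"H1": ["31", "35B"], "H2": ["50", "65"], "H3": ["95", "102"]}
    },
    "chothia": {
      "light": {"L1": ["24", "34"], "L2": ["50", "56"], "L3": ["89", "97"]},
      "heavy": {"H1": ["26", "32"], "H2": ["52", "56"], "H3": ["95", "102"]}
    },
    "imgt": {
      "light": {"L1": ["27", "38"], "L2": ["56", "65"], "L3": ["105", "117"]},
      "heavy": {"H1": ["27", "38"], "H2": ["56", "65"], "H3": ["105", "117"]}
    }
  },
  "insertion_anchors": {
    "kabat": {
      "light": {"L1": "27", "L2": "54", "L3": "95"},
      "heavy": {"H1": "35", "H2": "52", "H3": "100"}
    },
    "chothia": {
      "light": {"L1": "30", "L2": "54", "L3": "95"},
      "heavy": {"H1": "31", "H2": "52", "H3": "100"}
    },
    "imgt": {
      "light": {"L1": "32", "L2": "60", "L3": "111"},
      "heavy": {"H1": "32", "H2": "60", "H3": "111"}
    }
  }
}
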