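[
  {
    "name": "pneumonia_lower_respiratory",
    "patterns": ["%pneumoni%", "%bronkitt%", "%luftveisinfeksjon%"],
    "appropriate_codes": ["R78", "R81"]
  },
  {
    "name": "diabetes",
    "patterns": ["%diabet%"],
    "appropriate_codes": ["T89", "T90", "W85"]
  },
  {
    "name": "tonsillitis",
    "patterns": ["%tonsi%"],
    "appropriate_codes": ["R72", "R76"]
  },
  {
    "name": "anaemia",
    "patterns": ["%anemi%"],
    "appropriate_codes": ["B78", "B80", "B81", "B82"]
  }
]
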