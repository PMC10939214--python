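{
  "area": 242623.0,
  "base_year": 1979,
  "flags": {
    "diet_is_synthetic": true,
    "other_production_as": "BA",
    "stanza_ages_assumed": true
  }
}
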