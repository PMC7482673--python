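[
  {"name": "Protein Sum", "kind": "sum",
   "numerator": ["Synapsin", "GluN1", "GluN2A", "GluN2B", "GluA2", "GABAAa1", "GABAAa3"],
   "provenance": "high_amplitude"},
  {"name": "GlutR Sum", "kind": "sum",
   "numerator": ["GluN1", "GluN2A", "GluN2B", "GluA2"],
   "provenance": "high_amplitude"},
  {"name": "GABAAR Sum", "kind": "sum",
   "numerator": ["GABAAa1", "GABAAa3"],
   "provenance": "high_amplitude"},
  {"name": "GlutR:GABAAR", "kind": "index",
   "numerator": ["GluN1", "GluN2A", "GluN2B", "GluA2"],
   "denominator": ["GABAAa1", "GABAAa3"],
   "provenance": "a_priori"},
  {"name": "GluN2A:GluN2B", "kind": "index",
   "numerator": ["GluN2A"], "denominator": ["GluN2B"],
   "provenance": "a_priori"},
  {"name": "GluN2B:GluA2", "kind": "index",
   "numerator": ["GluN2B"], "denominator": ["GluA2"],
   "provenance": "a_priori"},
  {"name": "GABAAa1:GABAAa3", "kind": "index",
   "numerator": ["GABAAa1"], "denominator": ["GABAAa3"],
   "provenance": "a_priori"},
  {"name": "GABAAa1:GluN2A", "kind": "index",
   "numerator": ["GABAAa1"], "denominator": ["GluN2A"],
   "provenance": "novel_pair"},
  {"name": "GluN2A:GluA2", "kind": "index",
   "numerator": ["GluN2A"], "denominator": ["GluA2"],
   "provenance": "novel_pair"}
]
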