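[
  {"name": "Protein Sum", "kind": "sum",
   "numerator": ["GluA2", "GluN1", "GluN2A", "GluN2B", "GABAAa1", "GABAAa3",
                 "Gephyrin", "PSD95", "VGLUT1", "VGAT"],
   "provenance": "high_amplitude"},
  {"name": "VGLUT", "kind": "sum",
   "numerator": ["VGLUT1"],
   "provenance": "high_amplitude"},
  {"name": "Receptors Sum", "kind": "sum",
   "numerator": ["GluA2", "GluN1", "GluN2A", "GluN2B", "GABAAa1", "GABAAa3"],
   "provenance": "high_amplitude"},
  {"name": "Scaffolding Sum", "kind": "sum",
   "numerator": ["Gephyrin", "PSD95"],
   "provenance": "high_amplitude"},
  {"name": "VGAT Sum", "kind": "sum",
   "numerator": ["VGAT"],
   "provenance": "high_amplitude"},
  {"name": "GluN2A:GluN2B", "kind": "index",
   "numerator": ["GluN2A"], "denominator": ["GluN2B"],
   "provenance": "a_priori"},
  {"name": "GABAAa1:GABAAa3", "kind": "index",
   "numerator": ["GABAAa1"], "denominator": ["GABAAa3"],
   "provenance": "a_priori"},
  {"name": "GlutR:GABAAR", "kind": "index",
   "numerator": ["GluA2", "GluN1", "GluN2A", "GluN2B"],
   "denominator": ["GABAAa1", "GABAAa3"],
   "provenance": "a_priori"},
  {"name": "VGLUT1:VGAT", "kind": "index",
   "numerator": ["VGLUT1"], "denominator": ["VGAT"],
   "provenance": "novel_pair"}
]
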