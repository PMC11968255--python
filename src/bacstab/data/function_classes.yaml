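# Broad vs specialized metabolic function classification (KEGG KO categories).
# Broad functions are widely shared housekeeping categories; specialized
# functions are taxonomically restricted (element cycling, degradation).
# Lookup is case-insensitive; names not listed are left unclassified.
broad_l2:
  - Amino acid metabolism
  - Carbohydrate metabolism
  - Membrane transport
  - Metabolism of cofactors and vitamins
broad_l3:
  - Base excision repair
  - Pyruvate metabolism
  - Cysteine and methionine metabolism
specialized_l3:
  - Nitrogen metabolism
  - Sulfur metabolism
  - Atrazine degradation
  - Xenobiotics biodegradation and metabolism
  - Metabolism of xenobiotics by cytochrome P450
  - Polycyclic aromatic hydrocarbon degradation
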