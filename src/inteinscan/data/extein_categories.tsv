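# Static extein-family -> functional-category mapping (one row per pair).
# Categories: nucleic_acid_binding, hydrolase, transferase, oxidoreductase.
# family	category
TerL1	nucleic_acid_binding
TerL1	hydrolase
TerL6	nucleic_acid_binding
TerL6	hydrolase
Pham3880	nucleic_acid_binding
Pham3880	hydrolase
RecB	nucleic_acid_binding
RecB	hydrolase
RDF	nucleic_acid_binding
RDF	hydrolase
TOPRIM	nucleic_acid_binding
TOPRIM	transferase
NT	nucleic_acid_binding
NT	transferase
DNMT1	nucleic_acid_binding
DNMT1	transferase
DNMT2	nucleic_acid_binding
DNMT2	transferase
PORT	nucleic_acid_binding
HEL	nucleic_acid_binding
HEL	hydrolase
TdS	nucleic_acid_binding
TdS	transferase
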