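# family	ref_column	plus_one	allowed_classes  (ref_column = last N-extein residue)
TerL1	66	T	class1
TerL1	67	C	class1,class3
TerL1	110	C	class1,class3
TerL1	125	C	class1,class3
TerL1	153	C	class1,class3
TerL6	183	C	class1,class3
Pham3880	100	C	class1,class3
RecB	124	C	class1,class3
RDF	85	C	class1,class3
TdS	134	C	class1,class3
TdS	160	C	class1,class3
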