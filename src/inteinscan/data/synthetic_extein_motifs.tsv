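# family	start	end	label  (0-based, half-open)
TerL1	60	68	walker_A
TerL1	150	157	walker_B
TerL6	180	188	c_motif
Pham3880	95	105	other
RecB	120	130	pd_dexk
RDF	80	92	metallophos
TdS	130	141	active_site
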