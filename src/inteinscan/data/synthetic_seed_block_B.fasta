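>B_seed1 synthetic class1-like
GERVAITPDHKFLT
>B_seed2 synthetic class1-like
GERVAITPDHKFLT
>B_seed3 synthetic class1-like
GERIAITPDHRFLT
>B_seed4 synthetic class1-like
GDRVAVTPDHKFLS
>B_seed5 synthetic class3-like
GERVAITPEHKWLT
>B_seed6 synthetic class3-like
GERVALTPDHKWLT
>B_seed7 synthetic class3-like
GKRVAITPDHKWMT
>B_seed8 synthetic class1-like
GERVSITPDHKFLT
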