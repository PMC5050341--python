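>A_seed1 synthetic class1-like
CLAEGTRIFD
>A_seed2 synthetic class1-like
CLAEGTRVFD
>A_seed3 synthetic class1-like
CLPEGTRIFD
>A_seed4 synthetic class1-like
SLAEGSRIFD
>A_seed5 synthetic class1-like
TLAEGTRIFE
>A_seed6 synthetic class1-like
CLAEGTKIFD
>A_seed7 synthetic class3-like
ALADGTRIFD
>A_seed8 synthetic class3-like
VLAEGTRLFD
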