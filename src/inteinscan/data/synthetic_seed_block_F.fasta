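>F_seed1 synthetic class1-like
VYDVGVEKH
>F_seed2 synthetic class1-like
VYDVGVEKH
>F_seed3 synthetic class1-like
VYDVGLEKH
>F_seed4 synthetic class1-like
VFDVGVERH
>F_seed5 synthetic class3-like
VYDCGVEKH
>F_seed6 synthetic class3-like
VYDCGVDKH
>F_seed7 synthetic class3-like
IYDCGVEKH
>F_seed8 synthetic class1-like
VYDVGVEKY
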