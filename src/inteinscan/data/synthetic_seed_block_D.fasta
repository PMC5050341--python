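>D_seed1 synthetic
WRNKVEFTIS
>D_seed2 synthetic
WRNKVEFTIS
>D_seed3 synthetic
WRNKVDFTIS
>D_seed4 synthetic
WKNKVEFTIS
>D_seed5 synthetic
WRNRVEFTLS
>D_seed6 synthetic
WRNKVEFSIS
>D_seed7 synthetic
YRNKVEFTIS
>D_seed8 synthetic
WRNKIEFTIT
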