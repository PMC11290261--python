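# The nine essential amino acids, as compartment-agnostic metabolite base ids.
# Both BiGG-style (his__L) and single-underscore (his_L) spellings are listed.
his__L
ile__L
leu__L
lys__L
met__L
phe__L
thr__L
trp__L
val__L
his_L
ile_L
leu_L
lys_L
met_L
phe_L
thr_L
trp_L
val_L
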