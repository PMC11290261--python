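# Default currency metabolites, one base id per line (compartment-agnostic,
# case-insensitive).  Override with --currency-list / config `currency_list`.
atp
adp
amp
nad
nadh
nadp
nadph
fad
fadh2
coa
h
h2o
pi
ppi
co2
o2
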