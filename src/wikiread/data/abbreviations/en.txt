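# English abbreviations that do not end a sentence (one per line,
# matched case-insensitively against the token before a period).
dr
mr
mrs
ms
prof
st
jr
sr
vs
etc
e.g
i.e
cf
ca
approx
fig
figs
vol
pp
ed
eds
et al
al
dept
inc
ltd
co
resp
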