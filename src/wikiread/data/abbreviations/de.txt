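# German abbreviations that do not end a sentence.
dr
prof
med
bzw
usw
ca
vgl
ggf
evtl
inkl
zzgl
nr
abb
tab
sog
bspw
z.b
u.a
d.h
o.ä
u.ä
jh
mio
mrd
s
str
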