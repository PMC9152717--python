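# Shell-style glob patterns over category titles (case-insensitive).
# Articles whose categories match are list-like survey content, not
# individual diseases. Illustrative defaults — replace for real corpora.
*by country
*by continent
lists of*
*liste*
люди с*
people with*
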