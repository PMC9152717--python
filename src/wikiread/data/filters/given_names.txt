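# Given names used to exclude biographic articles: a title whose first
# token is on this list is treated as a person page.
# Illustrative defaults — replace for real corpora.
john
james
mary
maria
anna
hans
karl
friedrich
ivan
olga
dmitri
елена
иван
ольга
александр
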