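# Glob patterns flagging articles tied to specific countries, cities or
# locations. The fictional place names keep the defaults harmless;
# replace for real corpora.
*genovia*
*ruritania*
*freedonia*
* in kanbalu
эпидемии в *
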