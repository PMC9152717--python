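# Russian abbreviations that do not end a sentence.
г
гг
в
вв
т.е
т.д
т.п
т.к
др
пр
см
ср
напр
рис
табл
млн
млрд
тыс
им
ул
стр
гл
п
пп
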