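# Title patterns for residual non-disease pages: organizations,
# societies, awareness days. Illustrative defaults — replace for real
# corpora.
*association*
*foundation*
*society*
*organisation*
*organization*
*awareness day*
*world*day*
*gesellschaft*
*stiftung*
*welttag*
*общество*
*день борьбы*
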