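# demonstration lexicon: family (user-replaceable)
family
mom*
dad*
mother*
father*
sister*
brother*
parent*
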