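# demonstration lexicon: health (user-replaceable)
sick*
ill*
pain*
doctor*
hospital*
medic*
therapy
disorder*
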