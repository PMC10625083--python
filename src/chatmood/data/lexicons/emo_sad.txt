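# demonstration lexicon: emo_sad (user-replaceable)
sad*
cry*
lonely
depress*
grief
gloomy
tear*
miserable
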