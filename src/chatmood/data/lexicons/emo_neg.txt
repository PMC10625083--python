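# demonstration lexicon: emo_neg (user-replaceable)
sad*
depress*
lonely
hate*
hurt*
cry*
gloomy
distress*
bad
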