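# demonstration lexicon: emo_anx (user-replaceable)
anxious
anxiety
worr*
nervous
afraid
scared
fear*
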