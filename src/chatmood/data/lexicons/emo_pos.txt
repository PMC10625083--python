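# demonstration lexicon: emo_pos (user-replaceable)
happy*
joy*
love*
good
great
blessed
amazing
wonderful
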