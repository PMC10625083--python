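# demonstration lexicon: pron_2nd (user-replaceable)
you
you're
you've
your
yours
yourself
u
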