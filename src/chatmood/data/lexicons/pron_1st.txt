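# demonstration lexicon: pron_1st (user-replaceable)
i
i'm
i've
i'll
i'd
me
my
mine
myself
we
us
our
ours
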