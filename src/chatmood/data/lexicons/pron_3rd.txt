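# demonstration lexicon: pron_3rd (user-replaceable)
he
she
it
they
him
her
them
his
hers
theirs
it's
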