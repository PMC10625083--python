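# demonstration lexicon: past_focus (user-replaceable)
was
were
did
had
ago
yesterday
used
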