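# demonstration lexicon: death (user-replaceable)
death
die*
dying
dead
suicid*
kill*
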