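# demonstration lexicon: auditory (user-replaceable)
hear*
heard
listen*
sound*
loud
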