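elated
overjoyed
enjoy
excited
proud
joyful
happy
feel blessed
blessed
amazing
wonderful
excellent
delighted
enthusiastic
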