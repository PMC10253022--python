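SY1: popcorn
SY2: corn
SY3: corn
SY4: corn
SY5: lotus_root
SY6: popcorn
SY7: popcorn
SY8: popcorn
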