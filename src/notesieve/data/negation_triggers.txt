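# one negation trigger phrase per line
no
not
never
without
denies
denied
negative for
no evidence of
no sign of
no signs of
free of
absence of
absent
ruled out
rules out
unlikely
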