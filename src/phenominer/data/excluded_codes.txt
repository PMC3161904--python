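R52
R05
L29
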