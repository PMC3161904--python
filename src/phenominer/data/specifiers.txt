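caused by
due to
secondary to
forårsaget af
som følge af
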