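mother
father
sister
brother
friend
wife
husband
son
daughter
mor
far
søster
bror
ven
hustru
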