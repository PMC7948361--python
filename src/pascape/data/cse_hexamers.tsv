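hexamer
AAUAAA
AUUAAA
UAUAAA
AGUAAA
AAGAAA
AAUAUA
AAUACA
CAUAAA
GAUAAA
AAUGAA
UUUAAA
ACUAAA
AAUAGA
AUUACA
AUUAUA
AACAAA
AUUAGA
AACAAG
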