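name	recognition
HindIII	AAGCTT
XhoI	CTCGAG
KpnI	GGTACC
BamHI	GGATCC
EcoRI	GAATTC
NotI	GCGGCCGC
XbaI	TCTAGA
NheI	GCTAGC
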