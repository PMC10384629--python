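aa	codon	fraction
A	GCC	0.38
A	GCT	0.29
A	GCA	0.23
A	GCG	0.10
R	AGG	0.22
R	AGA	0.21
R	CGG	0.19
R	CGC	0.17
R	CGA	0.12
R	CGT	0.09
N	AAC	0.57
N	AAT	0.43
D	GAC	0.56
D	GAT	0.44
C	TGC	0.52
C	TGT	0.48
Q	CAG	0.75
Q	CAA	0.25
E	GAG	0.60
E	GAA	0.40
G	GGC	0.33
G	GGA	0.26
G	GGG	0.23
G	GGT	0.18
H	CAC	0.60
H	CAT	0.40
I	ATC	0.50
I	ATT	0.34
I	ATA	0.16
L	CTG	0.40
L	CTC	0.20
L	CTT	0.13
L	TTG	0.13
L	CTA	0.08
L	TTA	0.06
K	AAG	0.61
K	AAA	0.39
M	ATG	1.00
F	TTC	0.57
F	TTT	0.43
P	CCC	0.31
P	CCT	0.31
P	CCA	0.28
P	CCG	0.10
S	AGC	0.24
S	TCC	0.22
S	TCT	0.19
S	TCA	0.15
S	AGT	0.15
S	TCG	0.05
T	ACC	0.35
T	ACA	0.29
T	ACT	0.25
T	ACG	0.11
W	TGG	1.00
Y	TAC	0.58
Y	TAT	0.42
V	GTG	0.46
V	GTC	0.25
V	GTT	0.17
V	GTA	0.12
*	TGA	0.52
*	TAA	0.28
*	TAG	0.20
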