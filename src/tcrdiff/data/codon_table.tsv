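amino_acid	codon
A	GCC
R	AGA
N	AAC
D	GAC
C	TGC
Q	CAG
E	GAG
G	GGC
H	CAC
I	ATC
L	CTG
K	AAG
M	ATG
F	TTC
P	CCC
S	AGC
T	ACC
W	TGG
Y	TAC
V	GTG
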