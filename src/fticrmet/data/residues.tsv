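code	name	formula
G	Gly	C2H3NO
A	Ala	C3H5NO
S	Ser	C3H5NO2
P	Pro	C5H7NO
V	Val	C5H9NO
T	Thr	C4H7NO2
C	Cys	C3H5NOS
L	Leu	C6H11NO
I	Ile	C6H11NO
J	Nle	C6H11NO
N	Asn	C4H6N2O2
D	Asp	C4H5NO3
Q	Gln	C5H8N2O2
K	Lys	C6H12N2O
E	Glu	C5H7NO3
M	Met	C5H9NOS
H	His	C6H7N3O
F	Phe	C9H9NO
R	Arg	C6H12N4O
Y	Tyr	C9H9NO2
W	Trp	C11H10N2O
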