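symbol	monoisotopic_mass	nominal_mass	isotope_shift	isotope_abundance
H	1.00782503207	1	1.00627674589	0.000115
C	12.0	12	1.0033548378	0.0107
N	14.0030740048	14	0.9970348893	0.003642
O	15.9949146196	16	1.0042171777	0.000380
P	30.97376163	31	0.0	0.0
S	31.97207100	32	0.9993877	0.0075
Na	22.98976928	23	0.0	0.0
K	38.96370649	39	1.99811923	0.000117
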