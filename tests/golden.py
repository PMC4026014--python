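"""Frozen reference assignments used across the suite.

Published putative identifications from a rabbit-CSF FTICR-MS survey:
lipid-class masses with assigned formulas, and peptide-fragment masses
with both the assigned formula and the amino-acid composition (one-letter
codes; J = norleucine).  Detected masses are neutral, in Da.
"""

# (detected neutral mass, formula string as printed)
GOLDEN_LIPIDS = [
    (394.2846, "C_20_H_43_O_5_P"),
    (422.3158, "C_22_H_47_O_5_P"),
    (450.3471, "C_24_H_51_O_5_P"),
    (410.2793, "C_20_H_43_O_6_P"),
    (632.5132, "C_36_H_73_O_6_P"),
    (646.5281, "C_37_H_75_O_6_P"),
    (660.5457, "C_38_H_77_O_6_P"),
    (706.5527, "C_39_H_79_O_8_P"),
    (618.498, "C_35_H_71_O_6_P"),
    (674.5236, "C_38_H_75_O_7_P"),
]

# (detected neutral mass, formula, residue composition, nterm mod, cterm mod)
GOLDEN_PEPTIDES = [
    (1030.579, "C_48_H_78_N_12_O_13_", "ILNHIVPPE", None, None),
    (674.2703, "C_34_H_38_N_6_O_9_", "GYYWS", None, None),
    (672.2733, "C_31_H_40_N_6_O_11_", "DYYVN", None, None),
    (704.3001, "C_28_H_48_N_8_O_9_S_2_", "CAVVPNC", None, None),
    (398.288, "C_20_H_38_N_4_O_4_", "LLJ", "acetyl", "amide"),
    (918.3372, "C_43_H_50_N_8_O_15_", "GDEYYWS", None, None),
    (817.4655, "C_34_H_63_N_11_O_12_", "GSSKSKPK", None, None),
]

GOLDEN_ALL = GOLDEN_LIPIDS + [(m, f) for m, f, *_ in GOLDEN_PEPTIDES]
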