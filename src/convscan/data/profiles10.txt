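# name then 20 frequencies, residues ACDEFGHIKLMNPQRSTVWY
jtt-average 0.076748 0.019803 0.051544 0.061830 0.040126 0.073152 0.022944 0.053761 0.058676 0.091904 0.023826 0.042645 0.050901 0.040752 0.051691 0.068765 0.058565 0.066005 0.014261 0.032102
uniform 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000 0.050000
hydrophobic 0.198000 0.000667 0.000667 0.000667 0.000667 0.000667 0.000667 0.198000 0.000667 0.198000 0.198000 0.000667 0.000667 0.000667 0.000667 0.000667 0.000667 0.198000 0.000667 0.000667
aromatic 0.000588 0.000588 0.000588 0.000588 0.330000 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.330000 0.330000
basic 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.330000 0.000588 0.330000 0.000588 0.000588 0.000588 0.000588 0.000588 0.330000 0.000588 0.000588 0.000588 0.000588 0.000588
acidic 0.000556 0.000556 0.495000 0.495000 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556 0.000556
polar 0.000625 0.000625 0.000625 0.000625 0.000625 0.000625 0.000625 0.000625 0.000625 0.000625 0.000625 0.247500 0.000625 0.247500 0.000625 0.247500 0.247500 0.000625 0.000625 0.000625
small 0.330000 0.000588 0.000588 0.000588 0.000588 0.330000 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.000588 0.330000 0.000588 0.000588 0.000588 0.000588
proline 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.990000 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526
cysteine 0.000526 0.990000 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526 0.000526
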