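# Packaged amino-acid / silicon-nitride pore-wall interaction energies.
# Magnitudes are printed as -delta_E^AA in eV (all residues attractive);
# the loader negates them to recover the signed interaction energy.
# MET and ILE have no entry; lookups of absent codes raise KeyError.
code	minus_delta_e_ev	r_group_class
HIS	0.8913	positively charged
ARG	2.4674	positively charged
LYS	2.9291	positively charged
ASP	2.8251	negatively charged
GLU	2.7363	negatively charged
ASN	1.2610	uncharged polar
GLN	0.9411	uncharged polar
SER	1.4538	uncharged polar
THR	0.9887	uncharged polar
TYR	1.2834	uncharged polar
ALA	0.9876	nonpolar
VAL	0.9424	nonpolar
LEU	1.1341	nonpolar
PRO	1.0948	nonpolar
PHE	0.8881	nonpolar
TRP	1.0852	nonpolar
GLY	1.4880	nonpolar
CYS	1.4944	nonpolar
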