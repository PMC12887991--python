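# Amino-acid residue masses (Da).
# monoisotopic: most-abundant-isotope residue masses (IUPAC 2021 atomic masses),
# as used for peptide detectability; average: standard average residue masses
# (Expasy compute-pI/MW convention), used for protein molecular weight.
# Water: monoisotopic 18.0105646863, average 18.01528.
residue	monoisotopic	average
G	57.02146	57.05192
A	71.03711	71.07880
S	87.03203	87.07820
P	97.05276	97.11670
V	99.06841	99.13260
T	101.04768	101.10510
C	103.00919	103.13880
L	113.08406	113.15940
I	113.08406	113.15940
N	114.04293	114.10380
D	115.02694	115.08860
Q	128.05858	128.13070
K	128.09496	128.17410
E	129.04259	129.11550
M	131.04049	131.19260
H	137.05891	137.14110
F	147.06841	147.17660
R	156.10111	156.18750
Y	163.06333	163.17600
W	186.07931	186.21320
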