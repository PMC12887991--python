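# Modification-name -> Unimod biological-relevance class map.
# Editable; a name listed under more than one class is grouped as "Other"
# downstream (here: Methyl, which Unimod files both as a biological
# modification and as a chemical derivative).
mod_name	unimod_class
Phospho	Post-translational
Phosphoribosyl	Post-translational
Acetyl	Post-translational
Glutathione	Post-translational
Carboxy	Post-translational
Methyl	Post-translational
Methyl	Chemical derivative
Deamidated	Artefact
Oxidation	Artefact
Gln->pyro-Glu	Artefact
Carbamidomethyl	Chemical derivative
Carbamyl	Chemical derivative
TMT6plex	Isotopic label
iTRAQ4plex	Isotopic label
Label:13C(6)	Isotopic label
Label:13C(6)15N(2)	Isotopic label
Hex	Glycosylation
HexNAc	Glycosylation
Formyl	Co- or pre-translational
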