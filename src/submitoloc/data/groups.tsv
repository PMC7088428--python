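# Amino-acid grouping scheme: 10 functional groups (side-chain chemistry),
# 7 physico-chemical groups, and the residue classes used to label length-10
# short peptides. Groups may overlap; every residue belongs to at least one
# group of each category. Order of rows fixes feature order.
category	name	members
functional	aliphatic	AVLIG
functional	hydroxyl	ST
functional	sulfur	CM
functional	aromatic	FWY
functional	basic	KRH
functional	acidic	DE
functional	amide	NQ
functional	imino	P
functional	tiny	AG
functional	charged	DEKRH
physchem	hydrophobic	ACFILMVW
physchem	hydrophilic	DEKNQRH
physchem	neutral	GHPSTY
physchem	polar	CDEHKNQRSTY
physchem	nonpolar	AFGILMPVW
physchem	small	ACDGNPSTV
physchem	aromatic	FHWY
peptide	hydrophobic	FILMVW
peptide	hydrophilic	DEKR
peptide	neutral	GH
peptide	polar	CNQSTY
peptide	nonpolar	AP
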