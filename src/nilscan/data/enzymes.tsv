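name	recognition	cut_offset
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
EcoRV	GATATC	3
AluI	AGCT	2
HaeIII	GGCC	2
RsaI	GTAC	2
TaqI	TCGA	1
MspI	CCGG	1
HinfI	GANTC	1
DdeI	CTNAG	1
MboI	GATC	0
PstI	CTGCAG	5
SalI	GTCGAC	1
XbaI	TCTAGA	1
XhoI	CTCGAG	1
KpnI	GGTACC	5
SacI	GAGCTC	5
SmaI	CCCGGG	3
ApaI	GGGCCC	5
NcoI	CCATGG	1
NdeI	CATATG	2
SpeI	ACTAGT	1
SphI	GCATGC	5
NsiI	ATGCAT	5
ScaI	AGTACT	3
StuI	AGGCCT	3
DraI	TTTAAA	3
SspI	AATATT	3
BglII	AGATCT	1
ClaI	ATCGAT	2
AccI	GTMKAC	2
AvaI	CYCGRG	1
StyI	CCWWGG	1
AseI	ATTAAT	2
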