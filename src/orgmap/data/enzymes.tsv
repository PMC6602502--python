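# name	recognition (IUPAC, 5'->3')	cut offset (bases after position, top strand)
EcoRI	GAATTC	1
BamHI	GGATCC	1
HindIII	AAGCTT	1
NotI	GCGGCCGC	2
EcoRV	GATATC	3
SmaI	CCCGGG	3
XmaI	CCCGGG	1
XhoI	CTCGAG	1
SalI	GTCGAC	1
PstI	CTGCAG	5
KpnI	GGTACC	5
SacI	GAGCTC	5
SacII	CCGCGG	4
XbaI	TCTAGA	1
SpeI	ACTAGT	1
NcoI	CCATGG	1
NdeI	CATATG	2
NheI	GCTAGC	1
BglII	AGATCT	1
ClaI	ATCGAT	2
ApaI	GGGCCC	5
AatII	GACGTC	5
AflII	CTTAAG	1
AgeI	ACCGGT	1
AluI	AGCT	2
AscI	GGCGCGCC	2
AvrII	CCTAGG	1
BsrGI	TGTACA	1
BstBI	TTCGAA	2
DraI	TTTAAA	3
EagI	CGGCCG	1
FseI	GGCCGGCC	6
HaeIII	GGCC	2
HpaI	GTTAAC	3
HpaII	CCGG	1
MfeI	CAATTG	1
MluI	ACGCGT	1
MscI	TGGCCA	3
MseI	TTAA	1
NaeI	GCCGGC	3
NarI	GGCGCC	2
NsiI	ATGCAT	5
PacI	TTAATTAA	5
PmeI	GTTTAAAC	4
PvuI	CGATCG	4
PvuII	CAGCTG	3
RsaI	GTAC	2
ScaI	AGTACT	3
SnaBI	TACGTA	3
SphI	GCATGC	5
SspI	AATATT	3
StuI	AGGCCT	3
SwaI	ATTTAAAT	4
TaqI	TCGA	1
BsiWI	CGTACG	1
DdeI	CTNAG	1
SfiI	GGCCNNNNNGGCC	8
BstXI	CCANNNNNNTGG	8
AvaI	CYCGRG	1
FokI	GGATG	9
BsaI	GGTCTC	1
BbsI	GAAGAC	2
BanI	GGYRCC	1
HincII	GTYRAC	3
AccI	GTMKAC	2
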