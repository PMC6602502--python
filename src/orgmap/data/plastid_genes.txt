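# Canonical plastid gene names (locus-tag casing is authoritative).
# Shared by the gene-name tidy-up table and the fixture generator.
psbA
psbB
psbC
psbD
psbE
psbF
psbH
psbI
psbJ
psbK
psbL
psbM
psbN
psbT
psbZ
psaA
psaB
psaC
psaI
psaJ
petA
petB
petD
petG
petL
petN
atpA
atpB
atpE
atpF
atpH
atpI
ndhA
ndhB
ndhC
ndhD
ndhE
ndhF
ndhG
ndhH
ndhI
ndhJ
ndhK
rbcL
rpoA
rpoB
rpoC1
rpoC2
rps2
rps3
rps4
rps7
rps8
rps11
rps12
rps14
rps15
rps16
rps18
rps19
rpl2
rpl14
rpl16
rpl20
rpl22
rpl23
rpl32
rpl33
rpl36
clpP
matK
ccsA
cemA
accD
infA
ycf1
ycf2
ycf3
ycf4
rrn16
rrn23
rrn4.5
rrn5
trnH-GUG
trnK-UUU
trnQ-UUG
trnS-GCU
trnG-GCC
trnR-UCU
trnC-GCA
trnD-GUC
trnY-GUA
trnE-UUC
trnT-GGU
trnS-UGA
trnF-GAA
trnV-UAC
trnM-CAU
trnfM-CAU
trnW-CCA
trnP-UGG
trnL-UAA
trnL-CAA
trnI-GAU
trnA-UGC
trnN-GUU
trnR-ACG
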