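# Canonical mitochondrial gene names.
# Shared by the gene-name tidy-up table and the fixture generator.
nad1
nad2
nad3
nad4
nad4L
nad5
nad6
nad7
nad9
cox1
cox2
cox3
cob
atp1
atp4
atp6
atp8
atp9
sdh3
sdh4
ccmB
ccmC
ccmFC
ccmFN
rps3
rps12
rpl5
rpl16
matR
mttB
rrnS
rrnL
rrn5
rrn18
rrn26
trnM-CAU
trnW-CCA
trnF-GAA
trnP-UGG
trnY-GUA
trnD-GUC
trnK-UUU
trnE-UUC
trnS-UGA
trnQ-UUG
trnH-GUG
trnC-GCA
trnN-GUU
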