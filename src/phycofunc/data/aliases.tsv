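# gene symbol -> KEGG Orthology alias map for carbon-fixation key enzymes
aclA	K15230
aclB	K15231
mcr	K14468
rbcL	K01601
rbcS	K01602
prkB	K00855
abfD	K14534
acsB	K14138
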