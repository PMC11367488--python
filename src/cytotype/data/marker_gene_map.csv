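marker,gene
CD24,CD24
CD56,NCAM1
CD29,ITGB1
CD15,FUT4
CD184,CXCR4
CD133,PROM1
CD71,TFRC
CD44,CD44
GLAST,SLC1A3
AQP4,AQP4
HepaCAM,HEPACAM
CD140a,PDGFRA
O4,NKX6-2
SSEA-4,ST3GAL2
CD49f,ITGA6
TH,TH
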