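phenotype,parameter,mu,sigma
SL,CDT,-2.20,1.40
SL,WDT,-2.00,1.30
SL,TSL,-2.30,1.40
SL,PHS,0.60,1.00
SL,CPT,-0.80,1.10
SL,HPT,-1.20,1.20
SL,MPT,-1.20,1.60
SL,MPS,-0.80,1.10
SL,DMA,0.10,0.40
SL,PPT,-0.60,1.20
SL,WUR,0.20,1.00
SL,MDT,-1.90,1.70
SL,VDT,-1.80,1.60
TH,CDT,-0.20,1.00
TH,WDT,-0.40,1.00
TH,TSL,-0.30,1.00
TH,PHS,0.10,0.50
TH,CPT,0.70,1.30
TH,HPT,0.90,1.00
TH,MPT,0.10,1.10
TH,MPS,0.30,1.00
TH,DMA,0.20,0.60
TH,PPT,0.50,1.10
TH,WUR,0.30,1.10
TH,MDT,-0.20,1.00
TH,VDT,-0.30,1.00
MH,CDT,-1.30,1.30
MH,WDT,-1.40,1.20
MH,TSL,-1.50,1.30
MH,PHS,0.30,0.80
MH,CPT,0.20,1.20
MH,HPT,0.10,1.10
MH,MPT,1.40,1.30
MH,MPS,1.50,1.20
MH,DMA,1.60,1.30
MH,PPT,0.00,1.20
MH,WUR,0.60,1.20
MH,MDT,-0.90,1.40
MH,VDT,-0.80,1.30
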