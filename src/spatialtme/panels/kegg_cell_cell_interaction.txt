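# Cell-cell interaction molecule panel (editable default list: antigen
# presentation, adhesion and co-signaling molecules; curated, not a frozen
# database export).
HLA-A
HLA-B
HLA-C
HLA-E
HLA-F
HLA-DRA
HLA-DRB1
HLA-DPA1
HLA-DPB1
HLA-DQA1
HLA-DQB1
HLA-DMA
HLA-DMB
B2M
TAP1
TAP2
ICAM1
ICAM2
VCAM1
PECAM1
ITGAL
ITGAM
ITGB2
ITGA4
ITGB1
SELL
SELP
SELE
CD2
CD58
CD28
CD80
CD86
CD40
CD40LG
ICOS
ICOSLG
TNFRSF9
TNFSF9
LAG3
HAVCR2
TIGIT
PVR
NECTIN2
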