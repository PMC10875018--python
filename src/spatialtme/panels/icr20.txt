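# Immunologic Constant of Rejection (ICR) 20-gene panel.
# Th1 signaling / interferon
IFNG
TBX21
CD8A
CD8B
IL12B
STAT1
IRF1
# CXCR3/CCR5 chemoattraction
CXCL9
CXCL10
CCL5
# cytotoxic function
GNLY
PRF1
GZMA
GZMB
GZMH
# immune regulation
IDO1
CTLA4
CD274
PDCD1
FOXP3
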