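# Chemokine-signaling gene panel (editable default list of chemokines,
# their receptors and proximal signaling members; curated, not a frozen
# database export — edit freely or point the config at your own list).
CXCL1
CXCL2
CXCL5
CXCL8
CXCL9
CXCL10
CXCL11
CXCL12
CXCL13
CXCL14
CXCL16
CCL2
CCL3
CCL4
CCL5
CCL8
CCL11
CCL17
CCL19
CCL20
CCL21
CCL22
CX3CL1
XCL1
XCL2
CXCR3
CXCR4
CXCR5
CXCR6
CCR1
CCR2
CCR4
CCR5
CCR6
CCR7
CX3CR1
XCR1
JAK2
STAT3
PIK3CG
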