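node_a	node_b
STAT1	JAK1
STAT1	JAK2
STAT1	JAK3
STAT1	TYK2
STAT1	STAT2
STAT1	STAT3
STAT1	STAT4
STAT1	IFNGR1
STAT1	IFNGR2
STAT1	SOCS1
STAT1	SOCS3
STAT1	PIAS1
STAT1	PTPN6
STAT1	PTPN11
STAT1	IL6ST
STAT1	IL2RB
STAT1	GRB2
IL6	IL6R
IL6R	IL6ST
IL6ST	JAK1
IL6ST	JAK2
IFNG	IFNGR1
IFNGR1	IFNGR2
IL2	IL2RA
IL2	IL2RB
IL2RB	IL2RG
IL2RG	JAK3
JAK2	STAT5A
JAK2	STAT5B
JAK1	STAT3
JAK3	STAT5A
TYK2	STAT2
STAT3	SOCS3
STAT5A	SOCS2
STAT6	JAK1
STAT6	JAK3
PTPN11	GRB2
GRB2	SOS1
SOS1	PIK3CA
PIK3CA	AKT1
CRKL	JAK2
CRKL	SOS1
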