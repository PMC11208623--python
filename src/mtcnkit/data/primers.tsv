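name	target_gene	orientation	sequence	reported_tm
NEB-Fin-F1	NEB	forward	GGCACCTCTTGATATGCTCC	58.11
NEB-Fin-R1	NEB	reverse	TATGCCTTCTTGGCAAGGTCC	60.34
BECN1-Fin-F1	BECN1	forward	GAAGTTTTCCGGCGGCTAC	62
BECN1-Fin-R1	BECN1	reverse	CCGTCACCCAAGTCCGGT	64.4
ND1-Fin-F1	ND1	forward	CCAACCTCCTACTCCTCATTGT	59.21
ND1-Fin-R1	ND1	reverse	AGGGTTGTAGTAGCCCGTAG	59.21
ND6-Fin-F1	ND6	forward	ACTACAGCGATGGCTATTGAGG	60.7
ND6-Fin-R1	ND6	reverse	ATACTCTTTCACCCACAGCACC	60.4
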