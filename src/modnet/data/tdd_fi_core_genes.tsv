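gene_symbol	edge_count	in_degree	out_degree
EP300	115	24	91
SP1	85	72	13
RPS27A	84	62	22
JUN	77	32	45
UBC	73	72	1
SRC	71	61	10
RAC1	67	57	10
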