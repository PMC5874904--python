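subsystem	pre	post
Cofactors, vitamins, prosthetic groups, pigments	20	7
Cell wall and capsule	11	6
Virulence, disease, defense	2	1
Photosynthesis	2	2
Miscellaneous	2	0
Phage baseplate proteins	56	46
Phage replication	215	110
Phage packaging	144	37
Phage neck proteins	24	19
Phage lysogenic conversion modules	7	0
Phage Ea cluster	10	2
Phage lysis modules	116	43
Phage DNA synthesis	46	33
IbrA and IbrB: coactivators of prophage gene expression	2	0
Phage tail proteins	254	95
Phage virion particles involved in DNA ejection	11	10
Phage tail proteins 2	179	73
Phage nin genes-N-independent survival	17	0
Phage tail fiber proteins	139	67
Phage capsid proteins	198	86
Phage introns	19	5
Membrane transport	2	1
Iron acquisition and metabolism	2	1
RNA metabolism	1	0
Nucleosides and nucleotides	53	22
Protein metabolism	13	3
Regulation and cell signaling	22	1
DNA metabolism	6	2
Respiration	1	1
Stress response	11	7
Amino acids and derivatives	3	0
Sulfur metabolism	1	0
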