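microglia	cell-type markers	TMEM119	P2RY12	MERTK	CX3CR1
astrocyte	cell-type markers	AQP4	SLC1A2	GJA1
neuron	cell-type markers	RBFOX3	SYT1	SNAP25
oligodendrocyte	cell-type markers	PLP1	MBP	MOG
endothelial	cell-type markers	CLDN5	PECAM1	FLT1
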