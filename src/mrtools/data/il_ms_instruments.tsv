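exposure	SNP	gene	Chr	EA	EAF	beta_exposure	se_exposure	p_exposure	beta_outcome	se_outcome	p_outcome
IL-1Ra	rs1542176	RNU6-1180P	2	C	0.51	0.33	0.05	2.1 × 10^−12^	−0.01	0.02	0.44
IL-1Ra	rs6743376	IL1F10	2	C	0.31	0.46	0.05	2.4 × 10^−22^	−0.04	0.02	0.03
sIL-2Rα	rs12722497	IL2RA	10	A	0.14	0.63	0.05	1.6 × 10^−38^	0.12	0.03	3.2 × 10^−6^
IL-6	rs643434	ABO	9	G	0.62	−0.26	0.02	1.4 × 10^−48^	0.03	0.02	0.06
IL-6	rs56383622	IL6R	1	A	0.61	−0.23	0.02	1.3 × 10^−22^	0.03	0.02	0.05
IL-16	rs4778636	IL16	15	A	0.04	−0.73	0.06	1.1 × 10^−30^	0.03	0.03	0.36
IL-17	rs1530455	PDIA5	3	C	0.64	−0.11	0.02	4.7 × 10^−10^	−0.03	0.02	0.10
IL-18	rs2250417	BCO2	11	T	0.48	0.10	0.01	1.9 × 10^−32^	−0.02	0.02	0.32
IL-18	rs7577696	DPY30/SPAST	2	G	0.41	0.08	0.01	2.7 × 10^−19^	−0.01	0.02	0.46
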