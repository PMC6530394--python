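name	x	y	z	radius
Left IPS	-23	-70	46	6
Right IPS	25	-62	53	6
Left iPL	-42	-48	51	6
Right iPL	48	-41	54	6
Left vIPS	-26	-84	24	6
Right vIPS	35	-85	27	6
Left FEF	-24	-15	66	6
Right FEF	28	-10	58	6
IPCL	-55	-2	38	6
SMA	-2	-2	55	6
Left DLPFC	-40	39	30	6
Right DLPFC	38	41	26	6
Left vOC	-47	-71	-8	6
Right vOC	55	-64	-13	6
Left aIns	-45	35	9	6
Right aIns	45	3	15	6
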