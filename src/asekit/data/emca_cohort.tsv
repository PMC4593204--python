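sample_id	age	histology	rs937283	rs1690916	SNP55	SNP309
EMCA-1	53	Endometrioid(G1) + Squamous cell	A/G	A/G	C/T	T/G
EMCA-2	80	Endometrioid(G3)	A	G	C	G
EMCA-3	50	Endometrioid(G2) + Squamous cell	A/G	A/G	C/T	T
EMCA-4	51	Serous	A/G	A/G	C/T	T
EMCA-5	71	Endometrioid(G1)	G	A	T	T
EMCA-6	74	Serous	G	G	C/T	T
EMCA-7	76	Mixed + Serous	A/G	A/G	C/T	T
EMCA-8	42	Endometrioid(G1)	A	G	C	T/G
EMCA-9	58	Endometrioid(G1)	A	G	C	G
EMCA-10	54	Endometrioid(G3)	A/G	A/G	C/T	T/G
EMCA-11	39	Endometrioid(G1)	A/G	A/G	C/T	T/G
EMCA-12	62	Endometrioid(G2)	A/G	A/G	C/T	T
EMCA-13	71	Hetero	G	A	T	T
EMCA-14	66	Endometrioid(G2)	A	G	C	G
EMCA-15	81	Serous	A	G	C	T/G
EMCA-16	37	Endometrioid(G1)	A	G	C	G
EMCA-17	70	Endometrioid(G1)	A/G	A/G	C/T	T/G
EMCA-18	43	Endometrioid(G1)	G	A	T	T
EMCA-19	61	Serous	A/G	A/G	C/T	T/G
EMCA-20	77	Endometrioid(G2)	A/G	A/G	C/T	T/G
EMCA-21	74	Endometrioid(G1)	A	G	C	G
EMCA-22	56	Endometrioid(G2)	A/G	A/G	C/T	T/G
EMCA-23	42	Endometrioid(G1)	A	G	C	G
EMCA-24	55	Endometrioid(G1)	A/G	A/G	C/T	T/G
EMCA-25	69	Endometrioid(G1)	A/G	A/G	C/T	T/G
EMCA-26	65	Endometrioid(G1)	A	G	C	T/G
EMCA-27	56	Endometrioid(G2)	A/G	A/G	C/T	T
EMCA-28	83	Endometrioid(G2)	A	G	C	G
EMCA-29	58	Endometrioid(G2)	A	G	C	T
EMCA-30	78	Serous	A/G	A/G	C/T	T/G
EMCA-31	74	Endometrioid(G1)	A	G	C	G
EMCA-32	35	Endometrioid(G1)	A/G	A/G	C/T	T/G
EMCA-33	57	Endometrioid(G1)	A/G	A/G	C/T	T/G
EMCA-34	52	Endometrioid(G3) + Clear cell	A/G	A/G	C/T	T/G
EMCA-35	55	Endometrioid(G2)	G	A	T	T
EMCA-36	49	Endometrioid(G2)	A	G	C	T/G
EMCA-37	60	Endometrioid(G1)	A	G	C	G
EMCA-38	56	Endometrioid(G3)	A	G	C/T	T/G
EMCA-39	60	Endometrioid(G1)	G	A	T	T
EMCA-40	64	Endometrioid(G1)	A/G	A/G	C/T	T/G
EMCA-41	60	Endometrioid(G2)	G	A	T	T
EMCA-42	48	Endometrioid(G1)	A	G	C	G
EMCA-43	58	Clear cell	A	G	C	T/G
EMCA-44	58	Clear cell	A	G	C	T/G
EMCA-45	55	Endometrioid(G1)	A/G	A/G	C/T	T
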