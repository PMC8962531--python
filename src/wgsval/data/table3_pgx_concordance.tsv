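gene	row	n_samples	overall_num	overall_den
CYP2C19	CYP2C19*10	1	2	2
CYP2C19	CYP2C19*17	40	80	80
CYP2C19	CYP2C19*17/*17	1	2	2
CYP2C19	CYP2C19*2	48	96	96
CYP2C19	CYP2C19*2/*2	3	3	3
CYP2C19	CYP2C19*22	1	2	2
CYP2C19	CYP2C19*3	3	3	3
CYP2C19	CYP2C19*35	1	1	1
CYP2C19	CYP2C19*4	6	12	12
CYP2C19	CYP2C19*8	1	2	2
CYP2C19	CYP2C19*9	2	4	4
DPYD	DPYD c.1129-5923C>G	2	4	4
DPYD	DPYD c.1679T>G (*13)	3	6	6
DPYD	DPYD c.2846A>T	2	4	4
DPYD	DPYD*2 (c.1905+1G>A)	2	4	4
G6PD	G6PD A-202A_376G	3	6	6
G6PD	G6PD Canton, Taiwan-Hakka, Gifu-like, Agrigento-like	1	2	2
G6PD	G6PD Ilesha	2	4	4
G6PD	G6PD Mediterranean, Dallas, Panama, Sassari, Cagliari, Birmingham	5	10	10
G6PD	G6PD Seattle, Lodi, Modena, Ferrara II, Athens-like	1	2	2
G6PD	G6PD Union, Maewo, Chinese-2, Kalo	2	4	4
NUDT15	NUDT15*2	2	4	4
NUDT15	NUDT15*3	9	18	18
SLCO1B1	SLCO1B1*15	28	56	56
SLCO1B1	SLCO1B1*15/*15	4	8	8
SLCO1B1	SLCO1B1*17	3	6	6
SLCO1B1	SLCO1B1*5	8	16	16
TPMT	TPMT*2	6	12	12
TPMT	TPMT*3A	9	18	18
TPMT	TPMT*3C	5	10	10
UGT1A1	UGT1A1*27	3	6	6
UGT1A1	UGT1A1*28	70	140	140
UGT1A1	UGT1A1*36	12	24	24
UGT1A1	UGT1A1*36/*36	1	2	2
UGT1A1	UGT1A1*37	3	6	6
UGT1A1	UGT1A1*6	8	16	16
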