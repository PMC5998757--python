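method	start	target	rank	K
cooccurrence	INS	INSR	-	100
cooccurrence	INSR	IRS1/IRS	1	100
cooccurrence	IRS1/IRS	PI3K	3	100
cooccurrence	INSR	SOCS	10	100
cooccurrence	SOCS	IRS1/IRS	3	100
cooccurrence	IKK	IRS1/IRS	2	100
cooccurrence	JNK	IRS1/IRS	5	100
cooccurrence	PKCZ	IRS1/IRS	-	100
cooccurrence	PKCD/E	IRS1/IRS	4	100
cooccurrence	ADIPO	ADIPOR	1	100
cooccurrence	AMPKK	AMPK	1	100
cooccurrence	INSR	SHC	-	100
cooccurrence	SHC	GRB2	5	100
cooccurrence	GRB2	SOS	-	100
cooccurrence	SOS	Ras	-	100
cooccurrence	Ras	Raf	6	100
cooccurrence	Raf	MEK1/2	5	100
cooccurrence	MEK1/2	ERK1/2	1	100
cooccurrence	IRS1/IRS	GRB2	4	100
cooccurrence	PI3K	PDK1/2	2	100
cooccurrence	PDK1/2	AKT	4	100
cooccurrence	AKT	GLUT4	4	100
cooccurrence	PDK1/2	PKCZ	1	100
cooccurrence	PKCZ	GLUT4	2	100
cooccurrence	AKT	mTOR	1	100
cooccurrence	TNFA	TNFR1	1	100
cooccurrence	TNFA	TNFR2	1	100
cooccurrence	TNFR1	TRADD	-	100
cooccurrence	TRADD	TNFR2	-	100
cooccurrence	TNFR2	TRAF2	-	100
deepwalk	INS	INSR	-	100
deepwalk	INSR	IRS1/IRS	7	100
deepwalk	IRS1/IRS	PI3K	1	100
deepwalk	INSR	SOCS	6	100
deepwalk	SOCS	IRS1/IRS	2	100
deepwalk	IKK	IRS1/IRS	2	100
deepwalk	JNK	IRS1/IRS	4	100
deepwalk	PKCZ	IRS1/IRS	7	100
deepwalk	PKCD/E	IRS1/IRS	2	100
deepwalk	ADIPO	ADIPOR	1	100
deepwalk	AMPKK	AMPK	1	100
deepwalk	INSR	SHC	67	100
deepwalk	SHC	GRB2	16	100
deepwalk	GRB2	SOS	-	100
deepwalk	SOS	Ras	-	100
deepwalk	Ras	Raf	-	100
deepwalk	Raf	MEK1/2	4	100
deepwalk	MEK1/2	ERK1/2	1	100
deepwalk	IRS1/IRS	GRB2	4	100
deepwalk	PI3K	PDK1/2	6	100
deepwalk	PDK1/2	AKT	5	100
deepwalk	AKT	GLUT4	4	100
deepwalk	PDK1/2	PKCZ	1	100
deepwalk	PKCZ	GLUT4	3	100
deepwalk	AKT	mTOR	1	100
deepwalk	TNFA	TNFR1	6	100
deepwalk	TNFA	TNFR2	6	100
deepwalk	TNFR1	TRADD	-	100
deepwalk	TRADD	TNFR2	-	100
deepwalk	TNFR2	TRAF2	-	100
node2vec	INS	INSR	10	100
node2vec	INSR	IRS1/IRS	4	100
node2vec	IRS1/IRS	PI3K	1	100
node2vec	INSR	SOCS	8	100
node2vec	SOCS	IRS1/IRS	2	100
node2vec	IKK	IRS1/IRS	2	100
node2vec	JNK	IRS1/IRS	4	100
node2vec	PKCZ	IRS1/IRS	6	100
node2vec	PKCD/E	IRS1/IRS	2	100
node2vec	ADIPO	ADIPOR	1	100
node2vec	AMPKK	AMPK	1	100
node2vec	INSR	SHC	38	100
node2vec	SHC	GRB2	5	100
node2vec	GRB2	SOS	-	100
node2vec	SOS	Ras	-	100
node2vec	Ras	Raf	4	100
node2vec	Raf	MEK1/2	1	100
node2vec	MEK1/2	ERK1/2	1	100
node2vec	IRS1/IRS	GRB2	4	100
node2vec	PI3K	PDK1/2	1	100
node2vec	PDK1/2	AKT	3	100
node2vec	AKT	GLUT4	4	100
node2vec	PDK1/2	PKCZ	1	100
node2vec	PKCZ	GLUT4	3	100
node2vec	AKT	mTOR	1	100
node2vec	TNFA	TNFR1	6	100
node2vec	TNFA	TNFR2	4	100
node2vec	TNFR1	TRADD	-	100
node2vec	TRADD	TNFR2	-	100
node2vec	TNFR2	TRAF2	-	100
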