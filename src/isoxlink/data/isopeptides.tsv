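id	grain	gpt	tg2_lysine	tg2_peptide	gluten_peptide	xlink_q	xlink_ambiguous	deamidation	deam_ambiguous	accession	protein_name	organism	mq_score	prm_localized	unspecific_cleavage	note
W1	wheat	alpha-gliadins	K205	FLKNAGR	WQIPEQSR	2				P04726	alpha/beta-gliadin clone PW1215	T. aestivum	49.37	0	0
W2	wheat	gamma-gliadins	K205	FLKNAGR	AQIPQQL	2		5		A0A290XYW2	gamma-gliadin	T. aestivum	66.99	0	0	deamidation site reconstructed (figure annotation unavailable in transcription)
W3	wheat	gamma-gliadins	K205	FLKNAGR	VQGQGIIQPQQPAQL	10		4		P08453	gamma-gliadin	T. aestivum	91.31	0	0
W4	wheat	LMW-GS	K265	WKNHGCQR	PYSQPQPF	4				X2KVH9	alpha-gliadin	T. aestivum	59.21	0	0
W5	wheat	omega1,2-gliadins	K429	ISTKSVGR	PQQTFPQQPLF	8				R9XUE1	LMW-GS	T. aestivum	84.57	0	0	crosslink position follows the QP motif grouping and figure annotation; typeset table bolding (Q3) is inconsistent
W6	wheat	gamma-gliadins	K468	LAEKEETGMAMR	PQPPQQPF	2				A0A290XYS8	omega-gliadin	T. aestivum	75.31	0	1	unspecific cleavage at the C-terminal end (IP)
W7	wheat	gamma-gliadins	K590	DLYLENPEIKIR	VQGQGIIQPQQPAQL	10				P08453	gamma-gliadin	T. aestivum	61.21	0	0
W8	wheat	alpha-gliadins	K590	DLYLENPEIKIR	QEQQIGQEQQPGQW	9		3		B2LS24	HMW glutenin subunit type-2	T. timopheevii	55.26	1	0	deamidation site reconstructed (figure annotation unavailable in transcription)
W9	wheat	gamma-gliadins	K600	QKR	PQQSEQVIPQQPQQPF	6		10		A0A3B6UD61	uncharacterized protein	T. aestivum	104.05	1	0
W10	wheat	LMW-GS	K600	QKR	QQQPPFWQQQPPF	3		8		I3QPH0	low molecular weight glutenin subunit t128	T. aestivum	70.94	1	0
W11	wheat	alpha-gliadins	K677	AVKGFR	RPQQPYPQPQPQY	4				A0A023WGB8	alpha-gliadin	T. aestivum	63.73	0	0	crosslink position follows the QP motif grouping and figure annotation; typeset table bolding (Q3) is inconsistent
W12	wheat	alpha-gliadins	K677	AVKGFR	WQTPEQSR	2				I0IT59	alpha/beta-gliadin	T. aestivum	64.42	0	0
W13	wheat	HMW-GS	K677	AVKGFR	VYYPTSPQQPGQL	8				A0A1G4P1W4	HMW glutenin x-type subunit 1Bx6	T. aestivum	69.45	0	0
R1	rye	gamma-40k-secalins	K205	FLKNAGR	IVQGQSIIQQQPAQL	5		10		H8Y0N7	gamma prolamin	S. cereale ssp. afghanicum	68.97	1	0
R2	rye	gamma-75k-secalins	K429	ISTKSVGR	AQVQGIIQPQQL	2				A4GU91	75k gamma secalin	S. sylvestre	59.25	1	0
R3	rye	gamma-75k-secalins	K600	QKR	QPQQPFPQQPQQSF	12		1;11		H8Y0K1	gamma prolamin	P. juncea	80.75	1	0
R4	rye	gamma-75k-secalins	K677	AVKGFR	AQVQGIIQPQQL	2				A4GU91	75k gamma secalin	S. sylvestre	90.05	1	0
R5	rye	omega-secalins	K677	AVKGFR	QIPTPLQPQQPF	1				Q41210	C-hordein	H. vulgare	57.18	0	0
R6	rye	gamma-40k-secalins	K677	AVKGFR	AQIPQHL	2				H8Y0N7	gamma prolamin	S. cereale ssp. afghanicum	62.98	0	0
B1	barley	D-hordeins	K205	FLKNAGR	QGQQGQQLGQGQQGYY	7		13		A0A2C9PIB7	high-molecular-weight glutenin subunit protein	Ae. umbellulata	59.90	1	0
B2	barley	B-hordeins	K265	WKNHGCQR	VQQQQPPF	2		4		V9P6N2	LMW-i glutenin subunit 1	T. aestivum	85.85	0	0
B3	barley	D-hordeins	K590	DLYLENPEIKIR	PQQPGQW	2				I6TRS8	D-hordein	H. vulgare	44.97	0	0
B4	barley	gamma-hordeins	K590	DLYLENPEIKIR	IIPQQPQQPFPLQPHQPY		4|5			P17991	C-hordein	H. vulgare	44.20	0	1	both crosslinking sites possible; not assigned unambiguously even after PRM
B5	barley	D-hordeins	K600	QKR	PQQPGQGQQPGQR	2		8		I6TRS8	D-hordein	H. vulgare	121.20	0	0	crosslink position follows the QXP motif grouping and figure annotation; typeset table bolding (Q3) is inconsistent
B6	barley	D-hordeins	K600	QKR	PQQPGQGQGQQGYYPGATSL		10|11	8	10|11	I6TRS8	D-hordein	H. vulgare	82.36	0	1	second deamidation and crosslink ambiguous between Q10/Q11; deamidation at Q8 localized (77.4%)
B7	barley	gamma-hordeins	K677	AVKGFR	PLQPQQPFPW	5				Q41210	C-hordein	H. vulgare	72.55	1	0
B8	barley	gamma-hordeins	K677	AVKGFR	PQQQFPQQQFHQQQL	9		2;3;12	13|14	A0A0B5JD29	omega-gliadin	T. aestivum	52.73	0	0	crosslink at Q9 confirmed by targeted follow-up; fourth deamidation ambiguous between Q13/Q14
B9	barley	gamma-hordeins	K677	AVKGFR	FPQYQIPTPL	3		5		Q40053	Hor1-17 C-hordein	H. vulgare	47.94	1	0
B10	barley	D-hordeins	K677	AVKGFR	PQQPGQGQGQQGYYPGATSL	10				I6TRS8	D-hordein	H. vulgare	106.36	1	0
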