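# synthetic 38-entry hotspot panel fixture (seeded; coordinates are not real genomic loci)
#name	gene	chrom	pos	ref	alt
EGFR-T790M	EGFR	chrS0	1398	A	C
EGFR-L858R	EGFR	chrS1	3300	C	G
BRAF-V600E	BRAF	chrS2	5242	G	A
PIK3CA-E545K	PIK3CA	chrS3	7464	A	G
KRAS-G12C	KRAS	chrS0	9271	G	A
KRAS-G12V	KRAS	chrS1	11474	A	T
GENE06-X6	GENE06	chrS2	13434	T	C
GENE07-X7	GENE07	chrS3	15255	C	A
GENE08-X8	GENE08	chrS0	17497	C	G
GENE09-X9	GENE09	chrS1	19068	C	T
GENE10-X10	GENE10	chrS2	21123	C	T
GENE11-X11	GENE11	chrS3	23256	G	C
GENE12-X12	GENE12	chrS0	25419	T	G
GENE13-X13	GENE13	chrS1	27490	G	T
GENE14-X14	GENE14	chrS2	29154	A	C
GENE15-X15	GENE15	chrS3	31241	G	T
GENE16-X16	GENE16	chrS0	33464	T	C
GENE17-X17	GENE17	chrS1	35117	G	T
GENE18-X18	GENE18	chrS2	37443	G	T
GENE19-X19	GENE19	chrS3	39064	T	G
GENE20-X20	GENE20	chrS0	41342	T	C
GENE21-X21	GENE21	chrS1	43041	C	A
GENE22-X22	GENE22	chrS2	45151	T	G
GENE23-X23	GENE23	chrS3	47073	C	A
GENE24-X24	GENE24	chrS0	49038	T	G
GENE25-X25	GENE25	chrS1	51450	A	G
GENE26-X26	GENE26	chrS2	53305	T	A
GENE27-X27	GENE27	chrS3	55100	A	C
GENE28-X28	GENE28	chrS0	57363	C	G
GENE29-X29	GENE29	chrS1	59453	C	G
GENE30-X30	GENE30	chrS2	61372	G	T
GENE31-X31	GENE31	chrS3	63008	C	T
GENE32-X32	GENE32	chrS0	65002	C	A
GENE33-X33	GENE33	chrS1	67229	T	A
GENE34-X34	GENE34	chrS2	69428	T	G
GENE35-X35	GENE35	chrS3	71017	A	G
GENE36-X36	GENE36	chrS0	73036	A	T
GENE37-X37	GENE37	chrS1	75154	G	A
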