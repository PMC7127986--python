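# Gene locus table (1-based inclusive coordinates, GRCh37). Used to place
# coordinate-free categorical variants (amplification, oncogenic mutation, ...)
# onto full gene coordinates. GENE1/GENE2 are synthetic test loci.
gene	assembly	chromosome	start	end
BRAF	GRCh37	7	140419127	140624564
ERBB2	GRCh37	17	37844393	37884915
KRAS	GRCh37	12	25358180	25403854
EGFR	GRCh37	7	55086725	55275031
PIK3CA	GRCh37	3	178866311	178952497
TP53	GRCh37	17	7571720	7590868
ALK	GRCh37	2	29415640	30144432
PTEN	GRCh37	10	89623195	89728532
NRAS	GRCh37	1	115247085	115259515
FLT3	GRCh37	13	28577411	28674729
KIT	GRCh37	4	55524085	55606881
ABL1	GRCh37	9	133589333	133763062
MET	GRCh37	7	116312459	116438440
RET	GRCh37	10	43572517	43625799
ROS1	GRCh37	6	117609463	117747018
ERBB3	GRCh37	12	56473891	56497289
ERBB4	GRCh37	2	212240442	213403352
FGFR1	GRCh37	8	38268656	38326352
FGFR2	GRCh37	10	123237848	123357972
FGFR3	GRCh37	4	1795039	1810599
IDH1	GRCh37	2	209100951	209130798
IDH2	GRCh37	15	90626277	90645736
JAK2	GRCh37	9	4985033	5128183
NOTCH1	GRCh37	9	139388896	139440238
CDKN2A	GRCh37	9	21967751	21995300
CCND1	GRCh37	11	69455873	69469242
MYC	GRCh37	8	128748315	128753680
AKT1	GRCh37	14	105235686	105262088
MTOR	GRCh37	1	11166588	11322614
STK11	GRCh37	19	1205798	1228434
SMAD4	GRCh37	18	48556583	48611411
APC	GRCh37	5	112043195	112181936
RB1	GRCh37	13	48877887	49056122
VHL	GRCh37	3	10183319	10195354
NF1	GRCh37	17	29421945	29709134
ATM	GRCh37	11	108093211	108239829
BRCA1	GRCh37	17	41196312	41277500
BRCA2	GRCh37	13	32889611	32973805
ESR1	GRCh37	6	152011631	152424408
AR	GRCh37	X	66764465	66950461
KDR	GRCh37	4	55944644	55991756
PDGFRA	GRCh37	4	55095264	55164414
GENE1	GRCh37	1	1001	5000
GENE2	GRCh37	2	20001	28000
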