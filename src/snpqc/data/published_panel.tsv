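no	allele_id	allele_seq	chromosome	position	snp_change	trait	genetic_position
1	7557698|F|0-64:T>A-64:T>A	TGCAGATAATAATACAAAACGTGATTTCTATTGTGCACCTAGAAGTGAGCAGAGTTGTCTGCCATAAGT	Chr01	30898063	64:T>A		
2	100736260|F|0-18:C>T-18:C>T	TGCAGTCAGCGACTCTCTCCAATGATATTCTTCTTCTGGAGCTGAGTGGAACTTCTTTCTTTGATTCTA	Chr01	881461	18:C>T		
3	7629110|F|0-28:G>T-28:G>T	TGCAGTCTTTGCTCTCAAAAGTTTCTTTGGAGTTCTCATATGAATTCTGAACATCACTAATTTGGATTG	Chr02	13184152	28:G>T		
4	7609930|F|0-10:T>G-10:T>G	TGCAGTCATCTGTTTGTCTGAAGCAATTAGCCTATGATCTTGTTGAGCTGCTGTTGTCATCTGCATTTC	Chr02	6247633	10:T>G		
5	7629039|F|0-39:A>T-39:A>T	TGCAGTACAGAAAACCAACCAGCAGAAGATAATTTTTATAATGAACAGCTCAGGAACCCAGTTGGCTAG	Chr03	24217089	39:A>T		
6	7561292|F|0-28:A>G-28:A>G	TGCAGTTGACTCATCCCAACCGACCTACACATTATCAAAACAATTACAGATCGGAAGAGCGGTTCAGCA	Chr03	3304180	28:A>G		
7	11826044|F|0-66:G>A-66:G>A	TGCAGTCCATATCAGAATGACAATTCTGTAGAGATTGCACAATCCTTTGGGTTTTCTTCTGCGTACGAT	Chr04	31341133	66:G>A		
8	7569592|F|0-50:G>A-50:G>A	TGCAGAAGATGGTGGTTGCGACAGAATGAAAGAATGGAGTAAGCAGAGAAGGCCATTACCCCTTCTGAT	Chr04	5305718	50:G>A		
9	7552489|F|0-18:T>G-18:T>G	TGCAGATAAAAGGTAAAATCAAACCACAAATCTAACTGTCCTCTACATTCCTTTCTATCAAATATTTGG	Chr05	24475925	18:T>G		
10	7562059|F|0-41:A>G-41:A>G	TGCAGATGAAATGAAATGAAAACTTTTAGTGCATATCATGTAAGCAATGTAATTGAAATCCACTAAGAG	Chr05	892499	41:A>G		
11	9847708|F|0-17:G>C-17:G>C	TGCAGAAAAACATACGCGGTGGATTGATGGTTCTCAAACAAATGGAAGATGCAGAAGTGAAACCTGACT	Chr06	19672316	17:G>C		
12	7558428|F|0-52:C>T-52:C>T	TGCAGCTACAACTTTGACAAGCTGGCATCTATTAGTTACGTTTTGTTCCCTTCATGTGGCACTCTTGAT	Chr06	4639839	52:C>T		
13	9845663|F|0-25:T>G-25:T>G	TGCAGTTTATCTAAGTAAGATGATATTCAGCGAGATGAAAACCCTAGGATGAGTGTGAAGGAATACAAG	Chr07	23485155	25:T>G		
14	7618077|F|0-38:G>A-38:G>A	TGCAGATCTTGAGCAGGTTGTAAATAAAGTGTGAGAGTGAATTAGTTACCACAATTCTTGTAAATTTAG	Chr07	5042144	38:G>A		
15	100588703|F|0-44:T>C-44:T>C	TGCAGGCAACTTTATTGAAATGTTGACTAAAATCTTGTTTTCTGTCAAGCTTCAACATAGACCTCATTG	Chr08	15171824	44:T>C		
16	100512185|F|0-24:A>G-24:A>G	TGCAGTATCCGAAATCCCTTTCCAAATGTTTGCTTATAAGCTGGTTGAGAAGGAGAAAAGTTTAGGGAA	Chr08	6218106	24:A>G		
17	7568783|F|0-21:T>A-21:T>A	TGCAGTGCATGCATGAGCCTCTGGCAACGTTGAGAAGTCACCCGCTTGCAGTTTCTCGGTCACGTCGGT	Chr09	22534529	21:T>A		
18	14313832|F|0-18:G>A-18:G>A	TGCAGATATAATGAAAAAGCACATAAAAAGTGACAAGAAATTATCAAATTAGGTACACTTGCTGCATCT	Chr09	520352	18:G>A		
19	7554048|F|0-9:G>A-9:G>A	TGCAGTATCGAAAGCAATGTCTTTGGTCTTCTTGTTAGGTTTCTCTTCCTTTTCCATTTCTATTTCACA	Chr10	4446069	9:G>A		
20	7574585|F|0-20:A>G-20:A>G	TGCAGAAACTCCCAAAGGAGATAGGAAATTTGCATCATCTAAGGTACATTGATTTACAGATCGGAAGAG	Chr10	6952705	20:A>G		
21	7619107|F|0-63:G>T-63:G>T	TGCAGTGACGATTCTTCCAATTAGCTCTTCTGCCCTTGAACAACAATCAAACATAACTAGCTTGCTGTT	Chr11	18928235	63:G>T		
22	7611165|F|0-24:G>T-24:G>T	TGCAGTCAATCAGATAGAACAATCGTTTAGTCTTTAGTTATGGTGATTGATAGGGGGAGTATACGATTA	Chr11	2783237	24:G>T		
23	7558251|F|0-66:C>A-66:C>A	TGCAGCCACGTGACACCAACAAACCCCTATTTTTCCGCCCAGTTTTGTTCTCACTTGGCGGGAAACCCC	Chr12	1719732	66:C>A		
24	7619930|F|0-17:C>A-17:C>A	TGCAGAGGATAAAAGTTCTGTACCCAAACAGGGGCTTTTTACAGATCGGAAGAGCGGTTCAGCAGGAAT	Chr12	24038510	17:C>A		
25	7562142|F|0-54:C>T-54:C>T	TGCAGATTGTGTAATCCCTTTAGAGTCAGCAACAGAGGCACTCTCGGTGATTCTCTTCTCATTATTATC	Chr13	22402544	54:C>T		
26	100589662|F|0-45:C>T-45:C>T	TGCAGTAATGATTTGGATATAGCACATACACATATAAATTATATACAATATAGTATTATTTTCAGCAAA	Chr13	7074575	45:C>T		
27	100619651|F|0-17:C>T-17:C>T	TGCAGTTGCTTAGCTTCCGCTACTTTGTTGGGTGGCCTTCTCTTTGCAGGTAATTTGAAGTACTAATCA	Chr14	17915206	17:C>T		
28	15728547|F|0-52:T>A-52:T>A	TGCAGTTTTATTGAAGCTGAAAGTTTGATCAGAGAGGGAGAGAGAGTTTGAGTGAGGAAAAGAATGAAG	Chr14	3121906	52:T>A		
29	7559173|F|0-7:T>C-7:T>C	TGCAGTATATGTATTATCAAATATGTGAAACGAGAATGATGACAGGTCAATCTAGAAGTGTAGCACATT	Chr15	11417254	7:T>C		
30	9845617|F|0-25:C>A-25:C>A	TGCAGTTCCTGCACTTCCAGTGAACCCCGATATATATGCTCTCCGCATATAACACTCAGCAATGAATTC	Chr15	8808402	25:C>A		
31			Chr03	3185578	C>T	Dry matter & Starch	37.44
32			Chr03	2994719	C>G	Beta-carotene & Flesh color	36.14
33			Chr12	22131994	G>A	Beta-carotene & Flesh color	146.02
34			Chr12	22197168	T>A	Starch	147.31
35			Chr12	22369268	A>T	Dry matter	150.05
36			Chr15	452966	A>C	Storage root yield	4.19
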