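# Novel mature miRNAs identified in three rhesus macaque ESC lines, as printed
# (thousands separators stripped; precursor locations 1-based inclusive;
# multiple loci for one name are semicolon-separated).
mature_sequence	precursor_locations	name	IVF1.2	IVF3.2	IVF3.3
TATGGAGGTCTCTGTCTGGCT	chr1:205,580,537-205,580,616:-	miR-1843-5p	124	159	152
TCTGATCGTTCCCCTCCATACA	chr1:205,580,537-205,580,616:-	miR-1843-3p	127	174	193
TGATGGGTGAATTTGTAGAAGG	chr1:70,976,129-70,976,208:-	miR-1262-3p	2557	2267	2150
GTTGGGACAAGAGAACGGTCTT	chr1:158,332,926-158,333,000:-	miR-3122-5p	252	371	214
AATTCCCTTATGGATAATCTGG	chr2:80,519,804-80,519,882:+	miR-3938-3p	138	227	104
CATGCTAGAACAGAAAGAATGGG	chr3:106,443,245-106,443,327:+	miR-3146-3p	37	120	61
TATTTTGAGTGTTTGGAATTGA	chr4:125,407,861-125,407,939:+	miR-3145-3p	35	36	31
GAAAATGATGAGTAGTGACTGATG	chr4:128,869,861-128,869,951:+	miR-3622-3p	72	243	73
AAGAGCTTTTGGGAATTCAGGTAG	chr5:144,708,317-144,708,405:-	miR-3140-3p	151	358	200
ATATACAGGGGGAGACTCTTAT	chr7:164,327,476-164,327,555:+;chr7:164,328,696-164,328,775:+	miR-1185-3p	52	176	105
CGGGAACGTCGAGACTGGAGC	chr7:164,844,819-164,844,896:-	miR-1247-3p	127	131	32
TTAGGGCCCTGGCTCCATCTCC	chr9:73,887,081-73,887,164:+	miR-1296-5p	33	123	53
TCGACCGGACCTCGACCGGCTCG	chr9:103,084,702-103,084,783:-	miR-1307-5p	291	872	944
ACTCGGCGTGGCGTCGGTCGTGG	chr9:103,084,702-103,084,783:-	miR-1307-3p	1936	3975	3030
GACTCTAGCTGCCAAAGGCGCT	chr11:98,713,141-98,713,223:+	miR-1251-5p	40	97	59
TGTGGGACCTCTGGCCTTGGC	chr11:105,706,113-105,706,195:+	miR-3922-3p	192	250	248
TGCGGGGCTAGGGCTAACAGCA	chr16:11,829,804-11,829,901:+	miR-744-5p	11447	24797	14171
CTGTTGCCACTAACCTCAACC	chr16:11,829,804-11,829,901:+	miR-744-3p	75	81	104
TTTCCGGCTCGCGTGGGTGTGT	chr16:18,891,345-18,891,423:-	miR-1180-3p	30	133	77
CCGTCCTAAGGTTGTTGAGTT	chrX:68,990,098-68,990,174:+	miR-676-3p	46	206	206
TTCATTCGGCTGTCCAGATGTA	chrX:113,236,410-113,236,505:+	miR-1298-5p	246	893	852
CATCTGGGCAACTGACTGAACT	chrX:113,236,410-113,236,505:+	miR-1298-3p	30	98	58
TGAGTACCGCCATGTCTGTTGGG	chrX:113,271,154-113,271,232:+	miR-1911-5p	88	843	473
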