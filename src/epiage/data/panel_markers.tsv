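marker	chrom	start	end	strand	amplicon_size	fwd_primer	rev_primer	primer_conc_uM	reference_seq
FHL2	chr2	105399250	105399416	+	167	TGTTTTTAGGGTTTTGGGAGTATAG	ACACCTCCTAAAACTTCTCCAATCTCC	0.2	TGTTTTTAGGGTTTTGGGAGTATAGTGTCACTCGTCTCGCAGGACTACGAGCAATCACGTTTAGTGTCGGGCAGAGACGACTGAAGACGAGTGGAAGCGGAAATCAACGTTAGTGGGCGGTAGGCTATATGTACAGTTATGGAGATTGGAGAAGTTTTAGGAGGTGT
KLF14	chr7	130734307	130734434	+	128	GGTTTTAGGTTAAGTTATGTTTAATAGT	ACTACTACAACCCAAAAATTCC	0.2	GGTTTTAGGTTAAGTTATGTTTAATAGTTGCACCTTACTGAGTAACGACGTTTATATGGCCACCTCGGCGAGGTAGGGTGCACAGGTTAATTCACTAAGTGAAGTAGGAATTTTTGGGTTGTAGTAGT
TRIM59	chr3	160450140	160450280	+	141	TATAGGTGGTTTGGGGGAGAG	AAAAAACACTACCCTCCACAACATAAC	0.2	TATAGGTGGTTTGGGGGAGAGTGATTATCGTGGGTGATCGCTGTTATACGTCCAGCAGCGAGCGCAACTCACACGAATGGGTGCGAGGCTGTTCGTCTGGCTAGCATTTGTTAGGTTATGTTGTGGAGGGTAGTGTTTTTT
ELOVL2	chr6	11044500	11044766	+	267	AGGGGAGTAGGGTAAGTGAG	AAACCCAACTATAAACAAAACCAA	0.2	AGGGGAGTAGGGTAAGTGAGGTTGAAAGATCCCATGCGGGGGGTATTTATTTATGGATGTTATATCGTGGGAAGGTGGAAGAGAGTCTGATTGTCGTTGAAGAAGCATGTTAAATAGGGATAGCGAGTCGATAGCGATGGACTGACTAATATGATCGGTATAGTATACGGTGAAGGAGGTAATGTTTAGTTTGAGTCGGTAGAGTTACCAGTTTTGCTAAGATAGTAGTCATTTAAGGCTAAATTGGTTTTGTTTATAGTTGGGTTT
MIR29B2CHG	chr1	207823605	207823750	+	146	GTAAATATATAAGTGGGGGAAGAAGGG	TTAATAAAACCAAATTCTAAAACATTC	0.4	GTAAATATATAAGTGGGGGAAGAAGGGTTCTAAGAGATCCACTACATTCGTAAATACTTTGATACTGCGGATAAGGCGTGGTTGGACAGGTGACTTTAACAGCTGGGAAGGCAGGAGGTGAATGTTTTAGAATTTGGTTTTATTAA
EDARADD	chr1	236394309	236394501	-	193	TTGGTGATTAGGAGTTTTAGTGTTTT	CCACCTACAAATTCCCCAAA	0.4	TTGGTGATTAGGAGTTTTAGTGTTTTAGTGGGGATGGGGGTTGTGTTTATATGTGAATAAGTCGTGGGGTTGCTGAATAAGGCTCTCTTTGTTATGGTACTAACTTAGTTGTTTGGATCGTAATGAATAGGGGTTTTTCACAAAAAGTGAAAGGGGAGTGCCCTTCATAGTTGTTTGGGGAATTTGTAGGTGG
ASPA	chr17	3476207	3476314	+	108	TTTTGGAGGAATTTATGGGAA	ATAAATAATTTTACCTCCAACCCTA	0.4	TTTTGGAGGAATTTATGGGAATAGTAGTCCTGGAGTGGTAAGCCATCAGAGACAGCAATTCCTATACGCTGTGAGAGCCTGTATAGGGTTGGAGGTAAAATTATTTAT
PDE4C	chr19	18232953	18233167	+	215	TTGTAGGAGGAAAAGGGTTAG	AAAACAAAAACTTACAACAAATTAAA	1.0	TTGTAGGAGGAAAAGGGTTAGTTGCAAGTTGTTGCTACGGAAGGATGAATGAGGAGGAAGGATGTGCGAGGTGCTGCTATCAGGGTTTGCAAATACGAACTTGGAACATGAAGATAGCATTAGGCGGAGTATTAGAGATTTGACTATTGGGGCGGAGTGGTAGATTCTCTGGATCGTACGTTATAAGGTTTTAATTTGTTGTAAGTTTTTGTTTT
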