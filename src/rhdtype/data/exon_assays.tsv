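exon	fwd_id	fwd_seq	fwd_conc_um	rev_id	rev_seq	rev_conc_um	tm_c
1	RHD_E1_2f_M13	CAGGAAACAGCTATGACGCTTCCGTGTTAACTCCATAGAG	0.5	RHD_E1_2r	GGGGGAATCTTTTTCCTT	0.5	88.4
2	RHD-E2_936_F6	ATGACAGTAACAGCACGCAC	0.25	RHD_i2+61R7_M13	CAGGAAACAGCTATGACTATCCCAGATCTTCTGGAACC	0.25	89.0
3	Ds3s_M13	CAGGAAACAGCTATGACGTCGTCCTGGCTCTCCCTCTCT	0.25	RH_E3_r1	GAGATGAGGATCTTGCTATGATG	0.25	86.5
4	RHD_E4_1f_M13	CAGGAAACAGCTATGACTATCAGGGCTTGCCCC	0.25	RHD_E4_2r	TCAGACACCCAGGGGAAC	0.25	85.8
5	RH_E5_1f_M13	CAGGAAACAGCTATGACGACCTTTGGAGCAGGAGTG	0.15	RHD_E5_2r	TGTGACCACCCAGCATTCTA	0.15	88.7
6	Ds6a_M13	CAGGAAACAGCTATGACCTTCAGCCAAAGCAGAGGAGG	0.25	Ds6-s	CAGGGTTGCCTTGTTCCCA	0.25	88.3
7	RHD_E7_1f_M13	CAGGAAACAGCTATGACCCCCCTTTGGTGGCC	0.25	RHD_E7_2r	CTTTGGTCTATACCTAGGTGGC	0.25	87.1
8	RHD_E8_3f	GGAGGCTCTGAGAGGTTGAG	0.25	RH_E8_2r_M13	CAGGAAACAGCTATGACAATTATGTGATCCTCAGGGAAG	0.25	87.2
9	RHD_E9_2s_M13	CAGGAAACAGCTATGACTCCAGGAATGACAGGGCT	0.15	RH_E9_2r	TTAAGTTCATGCACTCAAAATCTAT	0.15	78.4
10	RH_E10_1f_M13	CAGGAAACAGCTATGACAGAGATCAAGCCAAAATCAGTAT	0.15	RHD_E10_1r	ATGGTGAGATTCTCCTCAAAG	0.15	85.6
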