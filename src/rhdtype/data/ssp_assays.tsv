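assay_name	target_allele	rs_id	fwd_id	fwd_seq	fwd_conc_um	rev_id	rev_seq	rev_conc_um	target_tm_c	ctrl_fwd_id	ctrl_fwd_seq	ctrl_rev_id	ctrl_rev_seq	ctrl_conc_um	ctrl_tm_c	discriminating_end
RHD*01W.1	RHD*01W.1	rs121912763	WD1-809G-f	acacgctatttctttgcagACTTATGG	0.25	WD1-r	GGTACTTGGCTCCCCCGAC	0.5	83.0	G107F	CTGGGCAGGTTGGTATCA	G107R	GAGAGTCAGTGCCTATCAGAAAC	0.25	80.7	fwd
RHD*01W.2	RHD*01W.2	rs71652374	WD2-1154C-f	ctccaaatcttttaacattaaattatgcatttaaacagC	0.5	WD2-r	gtgaaaaatcttacCTTCCAGAAAACTTGGTCATC	0.5	74.4	globin F	CAACTTCATCCACGTTCACC	globin R	GAAGAGCCAAGGACAGGTAC	0.25	86.0	fwd
RHD*01W.3	RHD*01W.3	rs144969459	WD3-8G-f	acagagacggacacaggATGAGATG	0.25	WD3-r	CTTGATAGGATGCCACGAGCCC	0.5	86.4	G107F	CTGGGCAGGTTGGTATCA	G107R	GAGAGTCAGTGCCTATCAGAAAC	0.25	80.7	fwd
RHD*07.01	RHD*07.01	rs121912762	RHD-E2-201-f	GCTTGGGCTTCCTCACCTCG	0.25	RHD-329C-r	ccaccatcccaatacCTGAACG	0.15	85.8	G107F	CTGGGCAGGTTGGTATCA	G107R	GAGAGTCAGTGCCTATCAGAAAC	0.25	80.7	rev
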