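allele_name	variants	structural_class	dropped_exons	category	phenotype_label	rs_ids	defining_exons
RHD*01		FULL_GENE		normal	normal D antigen
RHD*01N.01		GENE_ABSENT		D-negative	D-
RHD*01W.1	c.809T>G	FULL_GENE		weak D	weak D type 1	rs121912763	6
RHD*01W.2	c.1154G>C	FULL_GENE		weak D	weak D type 2	rs71652374	9
RHD*01W.3	c.8C>G	FULL_GENE		weak D	weak D type 3	rs144969459	1
RHD*01W.5	c.446C>A	FULL_GENE		weak D	weak D type 5		3
RHD*07.01	c.329T>C	FULL_GENE		partial D	DVII	rs121912762	2
RHD*04.03		EXON_DROPOUT	6,7,8,9	partial D	DIV type 3
RHD*01EL.01	c.1227G>A	FULL_GENE		DEL	Del		9
RHD*19	c.848C>T	FULL_GENE		partial D	DHMi		6
RHD*25	c.1063G>A	FULL_GENE		partial D	DNB		7
RHD*11	c.885G>T	FULL_GENE		weak partial D	weak partial type 11		6
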