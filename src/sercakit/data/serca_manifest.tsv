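pdb_id	isoform	cluster_label	state_label	exclusion_reason	tm_excluded
2c9m	SERCA1a	C1	E1-2Ca		0
1kju	SERCA1a		E2	low resolution	0
3j7t	SERCA1a		E1		0
4nab	SERCA1a		E1	missing regions	0
5zmw	SERCA1a	unassigned	E2-E1 intermediate (E309Q)		1
5ncq	SERCA1a	unassigned	E2 (THC-7 bound)		1
6rb2	SERCA1a		E1 (E340A)		0
6hxb	SERCA2a		E1		0
5mpm	SERCA2a		E2 (CPA bound)		0
5ztf	SERCA2b		E1		0
6jju	SERCA2b		E1		0
4h1w	SERCA1a	C2	E1-Mg-SLN		0
3w5a	SERCA1a	C2	E1-Mg-SLN		0
4kyt	SERCA1a	C2	E1-PLB		0
3fps	SERCA1a		E2 (CPA bound)		0
3fgo	SERCA1a		E2 (CPA bound)		0
3fpb	SERCA1a		E2 (CPA bound)		0
4bew	SERCA1a		E2 (CPA bound)		0
4ycl	SERCA1a		E2 (CPA bound)		0
2o9j	SERCA1a		E2		0
2oa0	SERCA1a		E2		0
3ba6	SERCA1a		E1		0
3tlm	SERCA1a		E2		0
4y3u	SERCA1a		E1		0
4ycm	SERCA1a		E2		0
4ycn	SERCA1a		E2		0
5a3r	SERCA1a		E1		0
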