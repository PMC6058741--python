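count	b1	c2	published_class
52	DTGAD	GRDLL	PREDICTED_ACTIVE
17	DTGVD	GRDLL	PREDICTED_ACTIVE
4	DTRAD	GRDLL	POTENTIALLY_ACTIVE
4	DTEAD	GRDLL	POTENTIALLY_ACTIVE
3	DTGSD	GRDLL	POTENTIALLY_ACTIVE
3	DTGED	GRDLL	POTENTIALLY_ACTIVE
3	DTGAD	GQDLL	POTENTIALLY_ACTIVE
3	DTGAD	GKDLL	POTENTIALLY_ACTIVE
3	DTDAD	GRDLL	POTENTIALLY_ACTIVE
2	DTEVD	GRDLL	POTENTIALLY_ACTIVE
1	DTVVD	GRDLL	POTENTIALLY_ACTIVE
1	DTVAD	GRDLL	POTENTIALLY_ACTIVE
1	DTGVD	GRHLL	POTENTIALLY_ACTIVE
1	DTGVD	GKDLL	POTENTIALLY_ACTIVE
1	DTGTD	GRDLL	POTENTIALLY_ACTIVE
1	DTGMD	GRDLL	POTENTIALLY_ACTIVE
1	DTGID	GRDLL	POTENTIALLY_ACTIVE
1	DTGGD	GRDLL	POTENTIALLY_ACTIVE
1	DTGDD	GRDLL	POTENTIALLY_ACTIVE
1	DTGAN	GRDLL	POTENTIALLY_ACTIVE
1	DTGAN	GKDLL	POTENTIALLY_ACTIVE
1	DTGAD	GRELL	POTENTIALLY_ACTIVE
1	DTGAD	GRDIL	POTENTIALLY_ACTIVE
1	DTGAD	GQELL	POTENTIALLY_ACTIVE
1	DTAAD	GRDLL	POTENTIALLY_ACTIVE
4	DTGAD	RRDLL	PREDICTED_INACTIVE
3	DTGAD	ERDLL	PREDICTED_INACTIVE
2	HTGAD	GRDLL	PREDICTED_INACTIVE
2	DTVVD	GGTLL	PREDICTED_INACTIVE
2	WAWAV	GWDLL	PREDICTED_INACTIVE
1	VTGVD	GRDLL	PREDICTED_INACTIVE
1	ITWGR	GVDN	PREDICTED_INACTIVE
1		GWDLL	PREDICTED_INACTIVE
1	ETGVD	GWDLL	PREDICTED_INACTIVE
1	DTVAD	GGDLL	PREDICTED_INACTIVE
1	DTRTD	GRDVL	PREDICTED_INACTIVE
1	DTRSD	GRDLL	PREDICTED_INACTIVE
1	DTRMD	GKEIY	PREDICTED_INACTIVE
1	DTRAD	GWDPL	PREDICTED_INACTIVE
1	DTGVD	LSPHTFI	PREDICTED_INACTIVE
1	DTGVA	GRDLL	PREDICTED_INACTIVE
1	DTGPD		PREDICTED_INACTIVE
1	DTGVD	RRDLL	PREDICTED_INACTIVE
1	DTGAD	VWDLL	PREDICTED_INACTIVE
1	DTGAD	GVDLL	PREDICTED_INACTIVE
1	DTGAD	GTRPI	PREDICTED_INACTIVE
1	DTGAD	GRYLL	PREDICTED_INACTIVE
1	DTGAD	GHLL	PREDICTED_INACTIVE
1	DTEAD	GQDLL	PREDICTED_INACTIVE
1	DRGMD	GRDLL	PREDICTED_INACTIVE
1	DMGAD	DQDLL	PREDICTED_INACTIVE
1	DMGAD		PREDICTED_INACTIVE
1	DIGVD	GRDLL	PREDICTED_INACTIVE
1	DIGAD	GGDLL	PREDICTED_INACTIVE
1	DIGAD	ERDLLL	PREDICTED_INACTIVE
1	DAGAD	GRDLL	PREDICTED_INACTIVE
1	ATGAD	GRDLL	PREDICTED_INACTIVE
1	ALGAD	RRDLL	PREDICTED_INACTIVE
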