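OXPHOS_PLACEHOLDER	synthetic non-canonical OXPHOS symbol list packaged as a default example gene set	NDUFA1	NDUFA2	NDUFA3	NDUFA4	NDUFA5	NDUFA6	NDUFA7	NDUFA8	NDUFA9	NDUFA10	NDUFA11	NDUFA12	NDUFA13	NDUFB1	NDUFB2	NDUFB3	NDUFB4	NDUFB5	NDUFB6	NDUFB7	NDUFB8	NDUFB9	NDUFB10	NDUFB11	NDUFS1	NDUFS2	NDUFS3	NDUFS4	NDUFS5	NDUFS6	NDUFS7	NDUFS8	NDUFV1	NDUFV2	NDUFV3	NDUFAB1	NDUFC1	NDUFC2	SDHA	SDHB	SDHC	SDHD	UQCRB	UQCRC1	UQCRC2	UQCRFS1	UQCRH	UQCRQ	UQCR10	UQCR11	CYC1	CYCS	COX4I1	COX5A	COX5B	COX6A1	COX6B1	COX6C	COX7A2	COX7B	COX7C	COX8A	COX10	COX11	COX15	COX17	ATP5F1A	ATP5F1B	ATP5F1C	ATP5F1D	ATP5F1E	ATP5MC1	ATP5MC2	ATP5MC3	ATP5ME	ATP5MF	ATP5MG	ATP5PB	ATP5PD	ATP5PF	ATP5PO	ATP6V0B	ATP6V0E1	ATP6V1C1	ATP6V1D	ATP6V1E1	ATP6V1F	ATP6V1G1	IDH1	IDH2	IDH3A	IDH3B	IDH3G	MDH1	MDH2	FH	CS	ACO2	SUCLA2	SUCLG1	OGDH	DLAT	DLD	PDHA1	PDHB
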