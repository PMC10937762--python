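STING_CORE_SYNTHETIC	synthetic stand-in 25-gene cGAS-STING core pathway panel (sensor, adaptor, trafficking, kinase, transcription-factor and ISG readout members); replaceable by any user GMT	ATG9A	CGAS	CXCL10	DDX41	IFI16	IFIT1	IFIT3	IFNB1	IKBKE	IRF3	IRF7	ISG15	MX1	NFKB1	OAS1	RELA	SEC24C	STIM1	STING1	TBK1	TREX1	TRIM21	TRIM32	TRIM56	ULK1
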