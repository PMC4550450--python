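record_id	bin_id	order	family	genus	source
REC_OUTGROUP	BIN_OUTGROUP	Xiphosurida	Limulidae	Limulus	voucher
REC_BIN_Alphida_01_01	BIN_Alphida_01_01	Alphida	Alphida_F01	Alphida_F01_G1	mined
REC_BIN_Alphida_01_02	BIN_Alphida_01_02	Alphida	Alphida_F01	Alphida_F01_G1	voucher
REC_BIN_Alphida_02_01	BIN_Alphida_02_01	Alphida	Alphida_F02	Alphida_F02_G1	voucher
REC_BIN_Alphida_02_02	BIN_Alphida_02_02	Alphida	Alphida_F02	Alphida_F02_G1	voucher
REC_BIN_Alphida_03_01	BIN_Alphida_03_01	Alphida	Alphida_F03	Alphida_F03_G1	voucher
REC_BIN_Alphida_03_02	BIN_Alphida_03_02	Alphida	Alphida_F03	Alphida_F03_G1	voucher
REC_BIN_Alphida_04_01	BIN_Alphida_04_01	Alphida	Alphida_F04	Alphida_F04_G1	voucher
REC_BIN_Alphida_04_03	BIN_Alphida_04_03	Alphida	Alphida_F04	Alphida_F04_G1	mined
REC_BIN_Alphida_04_02	BIN_Alphida_04_02	Alphida	Alphida_F04	Alphida_F04_G2	voucher
REC_BIN_Alphida_04_04	BIN_Alphida_04_04	Alphida	Alphida_F04	Alphida_F04_G2	voucher
REC_BIN_Betida_01_01	BIN_Betida_01_01	Betida	Betida_F01	Betida_F01_G1	voucher
REC_BIN_Betida_01_02	BIN_Betida_01_02	Betida	Betida_F01	Betida_F01_G1	voucher
REC_BIN_Betida_02_01	BIN_Betida_02_01	Betida	Betida_F02	Betida_F02_G1	voucher
REC_BIN_Betida_02_02	BIN_Betida_02_02	Betida	Betida_F02	Betida_F02_G1	voucher
REC_BIN_Betida_02_03	BIN_Betida_02_03	Betida	Betida_F02	Betida_F02_G1	mined
REC_BIN_Betida_03_01	BIN_Betida_03_01	Betida	Betida_F03	Betida_F03_G1	voucher
REC_BIN_Betida_03_02	BIN_Betida_03_02	Betida	Betida_F03	Betida_F03_G1	voucher
REC_BIN_Betida_03_03	BIN_Betida_03_03	Betida	Betida_F03	Betida_F03_G1	voucher
REC_BIN_Gammida_01_01	BIN_Gammida_01_01	Gammida	Gammida_F01	Gammida_F01_G1	mined
REC_BIN_Gammida_01_02	BIN_Gammida_01_02	Gammida	Gammida_F01	Gammida_F01_G1	mined
REC_BIN_Gammida_01_03	BIN_Gammida_01_03	Gammida	Gammida_F01	Gammida_F01_G1	voucher
REC_BIN_Gammida_02_01	BIN_Gammida_02_01	Gammida	Gammida_F02	Gammida_F02_G1	voucher
REC_BIN_Gammida_02_02	BIN_Gammida_02_02	Gammida	Gammida_F02	Gammida_F02_G1	voucher
REC_BIN_Gammida_02_03	BIN_Gammida_02_03	Gammida	Gammida_F02	Gammida_F02_G1	voucher
REC_BIN_Gammida_03_01	BIN_Gammida_03_01	Gammida	Gammida_F03	Gammida_F03_G1	voucher
REC_BIN_Gammida_03_02	BIN_Gammida_03_02	Gammida	Gammida_F03	Gammida_F03_G1	voucher
REC_BIN_Gammida_03_03	BIN_Gammida_03_03	Gammida	Gammida_F03	Gammida_F03_G1	mined
REC_BIN_Deltida_01_01	BIN_Deltida_01_01	Deltida	Deltida_F01	Deltida_F01_G1	voucher
REC_BIN_Deltida_01_02	BIN_Deltida_01_02	Deltida	Deltida_F01	Deltida_F01_G1	voucher
REC_BIN_Deltida_01_03	BIN_Deltida_01_03	Deltida	Deltida_F01	Deltida_F01_G1	voucher
REC_BIN_Deltida_02_01	BIN_Deltida_02_01	Deltida	Deltida_F02	Deltida_F02_G1	voucher
REC_BIN_Deltida_02_02	BIN_Deltida_02_02	Deltida	Deltida_F02	Deltida_F02_G1	mined
REC_BIN_Deltida_02_03	BIN_Deltida_02_03	Deltida	Deltida_F02	Deltida_F02_G1	voucher
REC_BIN_Betida_02_03_NUMT	BIN_Betida_02_03	Betida	Betida_F02	Betida_F02_G1	mined
REC_BIN_Gammida_03_02_NUMT	BIN_Gammida_03_02	Gammida	Gammida_F03	Gammida_F03_G1	mined
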