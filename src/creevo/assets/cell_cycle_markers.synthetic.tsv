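stage	gene
G1	CYCD_00
G1	CYCD_01
G1	CYCD_02
G1	CYCD_03
G1	CYCD_04
G1	CYCD_05
G1	CYCD_06
G1	CYCD_07
G1	CYCD_08
G1	CYCD_09
G1	CYCD_10
G1	CYCD_11
G1	CYCD_12
G1	CYCD_13
G1	CYCD_14
G1	CYCD_15
G1	CYCD_16
G1	CYCD_17
S	HIS_00
S	HIS_01
S	HIS_02
S	HIS_03
S	HIS_04
S	HIS_05
S	HIS_06
S	HIS_07
S	HIS_08
S	HIS_09
S	HIS_10
S	HIS_11
S	HIS_12
S	HIS_13
S	HIS_14
S	HIS_15
S	HIS_16
S	HIS_17
G2M	CYCB_00
G2M	CYCB_01
G2M	CYCB_02
G2M	CYCB_03
G2M	CYCB_04
G2M	CYCB_05
G2M	CYCB_06
G2M	CYCB_07
G2M	CYCB_08
G2M	CYCB_09
G2M	CYCB_10
G2M	CYCB_11
G2M	CYCB_12
G2M	CYCB_13
G2M	CYCB_14
G2M	CYCB_15
G2M	CYCB_16
G2M	CYCB_17
G2M	CYCB_18
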