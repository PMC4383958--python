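!gaf-version: 2.1
!mini annotation set for the clade-restricted propagation example
MINI	CE_UNC1	CE_UNC1		GO:0002119	MINI:1	IMP		P	worm larval gene		protein	taxon:6239	20140101	MINI
MINI	AT_Q8VYZ5	AT_Q8VYZ5		GO:0009553	MINI:2	IMP		P	plant target gene		protein	taxon:3702	20140101	MINI
MINI	AT_Q8VYZ5	AT_Q8VYZ5		GO:0016072	MINI:3	IMP		P	plant target gene		protein	taxon:3702	20140101	MINI
MINI	AT_DEV2	AT_DEV2		GO:0009791	MINI:4	IDA		P	plant developmental gene		protein	taxon:3702	20140101	MINI
MINI	HS_X	HS_X		GO:0016072	MINI:5	IDA		P	human rRNA gene		protein	taxon:9606	20140101	MINI
MINI	HS_Y	HS_Y		GO:0008150	MINI:6	IEA		P	electronic only		protein	taxon:9606	20140101	MINI
MINI	CE_NOT	CE_NOT	NOT	GO:0009791	MINI:7	IMP		P	negated record		protein	taxon:6239	20140101	MINI
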