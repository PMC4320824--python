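effect_type	50A	51A	55A	WT1	WT2
FRAME_SHIFT	5	8	12	10	5
SPLICE_SITE_ACCEPTOR	1	0	0	1	0
SPLICE_SITE_DONOR	2	0	0	0	0
START_LOST	0	0	0	0	0
STOP_GAINED	1	0	0	0	0
STOP_LOST	2	0	0	0	0
CODON_CHANGE_PLUS_CODON_DELETION	0	1	1	0	2
CODON_CHANGE_PLUS_CODON_INSERTION	0	0	0	0	0
CODON_DELETION	2	1	5	1	5
CODON_INSERTION	0	1	0	0	0
NON_SYNONYMOUS_CODING	21	15	21	8	7
NON_SYNONYMOUS_START	0	0	0	0	0
SPLICE_SITE_REGION	3	0	0	0	3
START_GAINED	3	1	0	1	0
SYNONYMOUS_CODING	13	4	7	7	7
SYNONYMOUS_STOP	1	0	0	0	0
DOWNSTREAM	307	237	337	205	323
INTERGENIC	395	305	404	250	407
INTRAGENIC	0	0	0	0	0
INTRON	30	31	40	29	56
UPSTREAM	8	6	10	7	4
UTR_3_PRIME	1	4	2	0	2
UTR_5_PRIME	3	5	3	5	5
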