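# Published benchmark abstract-level confusion counts per characteristic
# and dataset split (training / development / evaluation).
# characteristic	dataset	tp	fp	fn
AGE	training	51	6	10
AGE	development	57	1	10
AGE	evaluation	47	1	11
SEX	training	52	5	5
SEX	development	54	6	5
SEX	evaluation	54	0	4
OFFENDER_TYPE	training	78	15	15
OFFENDER_TYPE	development	94	11	8
OFFENDER_TYPE	evaluation	98	8	19
NATIONALITY	training	36	3	3
NATIONALITY	development	32	5	1
NATIONALITY	evaluation	40	4	2
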