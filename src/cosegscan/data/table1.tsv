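# Familial cholesteatoma cohort: 21 participants in 10 multiply affected
# families. age_is_surgery_proxy=1 marks ages recorded at first surgery
# rather than diagnosis.
family_id	sample_id	age	age_is_surgery_proxy	bilateral	sex	relationship
1	1a	28	0	Y	female	Sister
1	1b	30	1	N	male	Child
2	2a	23	0	Y	male	Index
2	2b	11	0	N	male	Brother
3	3a	44	1	N	female	Index
3	3b	3	0	N	female	Child
3	3c	6	0	Y	female	Sister
4	4a	35	0	N	male	Index
4	4b	40	1	N	male	Brother
5	5a	1	0	Y	female	Index
5	5b	36	0	N	male	Child
6	6a	10	0	N	female	Index
6	6b	5	0	N	female	Maternal aunt
7	7a	1	0	N	female	Index
7	7b	63	0	N	male	Maternal grandfather
8	8a	11	0	N	female	Index
8	8b	6	0	N	male	Brother
9	9a	42	1	N	female	Index
9	9b	44	1	N	female	Mother
10	10a	1	0	Y	female	Index
10	10b	5	1	Y	female	Granddaughter
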