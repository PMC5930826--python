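accession	strain	genome_bp	gc_percent	cds	trnas	plasmids	prophages	is_elements
PDZF00000000	P7	3,169,294	41.4	3071	55	0	0 (6)	10
PDZE00000000	P3a	3,379,590	41.5	3238	50	0	0 (2)	11
PDZD00000000	P35	3,252,669	44.5	3247	59	1	2 (1)	16
PDZC00000000	P34	3,262,144	41.4	3203	44	0	1 (1)	8
PDZB00000000	P32b	3,314,266	41.3	3218	58	0	0 (2)	15
PDZA00000000	P31	3,316,673	41.3	3218	57	0	0 (2)	17
PDYZ00000000	P30	3,313,921	41.3	3215	58	0	0 (2)	15
PDYY00000000	P2a	3,328,642	41.3	3235	52	0	0 (1)	12
PDYX00000000	P29	3,382,122	41.4	3325	58	0	0 (2)	19
PDYW00000000	P26b	3,382,782	41.2	3246	50	0	0 (2)	11
PDYV00000000	P25	3,269,093	41.1	3182	51	0	0 (3)	13
PDYU00000000	P21c	3,384,350	42.2	3292	54	0	1 (0)	13
PDYT00000000	P20a	3,314,917	41.4	3228	56	0	0 (1)	12
PDYS00000000	P1a	3,306,654	41.2	3194	50	0	0 (2)	13
PDYR00000000	P19	3,339,001	41.4	3216	50	0	0 (3)	5
PDYQ00000000	P18a	3,219,274	41.4	3149	51	0	1 (1)	4
PDYP00000000	P17b	3,401,750	41.3	3336	60	0	1 (5)	11
PDYO00000000	P16b	3,363,873	41.1	3281	51	0	0 (1)	19
PDYN00000000	P16a	3,293,369	41.1	3185	56	0	0 (3)	12
PDYM00000000	P13	3,318,423	40.6	3234	54	0	1 (2)	16
PDYL00000000	P12	3,438,859	41.4	3372	56	0	0 (1)	16
PDYK00000000	P10	3,437,370	41.4	3374	47	0	0 (1)	15
CP015108	S204	3,362,333	41.5	3196	60	0	0 (1)	46
CP015027	P33	3,235,441	44.5	3050	68	0	1 (1)	29
CP015109	P17a	3,412,428	41.5	3204	68	0	0 (2)	15
CP015207	P8	3,353,765	41.2	3164	69	0	0 (3)	12
CP015348	P32a	3,382,744	41.4	3183	68	0	0 (4)	28
CP015349	P37	3,271,521	44.7	3155	68	1	2 (1)	37
NZ_AUDQ00000000	DSM 2281	3,318,232	41.4	3241	56	0	0 (2)	2
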