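clan	family	Jv	Ja	Ha	Ls	At
CYP51	CYP51	3	4	1	1	2
CYP71	CYP71	41	21	85	74	50
CYP71	CYP73	2	4	3	2	1
CYP71	CYP75	1	1	3	2	1
CYP71	CYP76	14	12	30	25	8
CYP71	CYP77	2	2	3	4	5
CYP71	CYP78	5	5	8	7	6
CYP71	CYP79	1	1	12	6	7
CYP71	CYP80	1	0	10	5	0
CYP71	CYP81	9	2	32	18	17
CYP71	CYP82	11	15	26	32	5
CYP71	CYP83	0	0	0	0	2
CYP71	CYP84	4	3	7	2	2
CYP71	CYP89	3	3	11	5	7
CYP71	CYP92	5	2	2	4	0
CYP71	CYP93	12	5	7	6	1
CYP71	CYP98	5	6	2	2	3
CYP71	CYP701	3	2	5	3	1
CYP71	CYP703	0	0	1	1	1
CYP71	CYP705	0	0	0	0	25
CYP71	CYP706	25	12	26	27	7
CYP71	CYP712	0	0	0	0	2
CYP71	CYP736	0	0	2	5	0
CYP72	CYP72	16	13	40	25	9
CYP72	CYP714	2	2	1	1	2
CYP72	CYP715	0	0	1	1	1
CYP72	CYP721	1	0	4	2	1
CYP72	CYP734	0	0	3	2	1
CYP72	CYP735	1	1	1	1	2
CYP72	CYP749	7	4	6	4	0
CYP74	CYP74	7	4	6	7	2
CYP85	CYP85	1	1	2	1	2
CYP85	CYP87	0	0	8	2	1
CYP85	CYP88	1	0	1	2	2
CYP85	CYP90	5	4	6	7	4
CYP85	CYP702	0	0	0	0	6
CYP85	CYP707	4	2	9	6	4
CYP85	CYP708	0	0	0	0	4
CYP85	CYP709	0	0	0	0	3
CYP85	CYP716	2	3	24	12	2
CYP85	CYP718	0	0	1	1	1
CYP85	CYP720	1	1	1	1	1
CYP85	CYP722	1	1	1	2	1
CYP85	CYP724	0	0	1	1	1
CYP85	CYP728	0	0	6	4	0
CYP85	CYP729	0	0	1	6	0
CYP85	CYP733	0	0	1	1	0
CYP86	CYP86	6	5	9	7	11
CYP86	CYP94	2	1	13	10	6
CYP86	CYP96	3	3	15	16	13
CYP86	CYP704	9	7	18	16	3
CYP97	CYP97	3	3	3	3	3
CYP710	CYP710	1	1	2	1	4
CYP711	CYP711	1	1	2	1	1
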