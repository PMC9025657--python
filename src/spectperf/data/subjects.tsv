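subject_id	epilepsy_group	sex	seizure_onset_y	age_y	epilepsy_duration_y	ez_laterality	seizures_awake	seizures_sleep	injection_time_s	electrographic_seizure_s	ictal_valid
TLE-1	TLE	F	34	35	1	right	17	3			False
TLE-2	TLE	F	6	21	15	left	6	1			False
TLE-3	TLE	F	8	32	24	left	6	1	7	97	True
TLE-4	TLE	F	0.8	33	33	left	4	5	17	72	True
FLE-1	FLE	M	6	21	15	right	4	1	2	95	True
FLE-2	FLE	M	4	15	11	right	96	5	8	45	True
FLE-3	FLE	F	14	15	1	right	6	10	4	16	False
FLE-4	FLE	M	11	31	20	right	27	2			False
FLE-5	FLE	M	0	23	23	right	6	1			False
FLE-6	FLE	M	18	21	3	left	4	1			False
FLE-7	FLE	M	3	17	14	left	6	2	10	14	False
FLE-8	FLE	M	3	28	25	right	2	3	5	20	True
PQE-1	PQE	F	18	29	11	right	7	5			False
PQE-2	PQE	F	9	25	16	right	8	3	3	34	True
PQE-3	PQE	M	8	18	10	left	6	0	6	8	True
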