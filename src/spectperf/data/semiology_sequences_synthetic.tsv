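subject_id	seizure_id	code	onset_s
TLE-1	s1	SENSA	3
TLE-1	s1	STAR	8
TLE-1	s1	OA	30
TLE-1	s1	INCS	42
TLE-1	s1	TEUL	48
TLE-1	s1	SEND	62
TLE-2	s1	SMELL	5
TLE-2	s1	STAR	9
TLE-2	s1	SPEAR	35
TLE-2	s1	OA	55
TLE-2	s1	SEND	70
TLE-3	s1	BLUR	4
TLE-3	s1	STAR	7
TLE-3	s1	OA	28
TLE-3	s1	VOCA	50
TLE-3	s1	TEUL	40
TLE-3	s1	SEND	75
TLE-4	s1	SLPY	6
TLE-4	s1	STAR	10
TLE-4	s1	INCS	60
TLE-4	s1	DUC	57
TLE-4	s1	OA	89
TLE-4	s1	SEND	95
FLE-1	s1	STAR	2
FLE-1	s1	ABU	3
FLE-1	s1	CLCU	8
FLE-1	s1	GTCC	24
FLE-1	s1	SEND	55
FLE-2	s1	DIZZ	2
FLE-2	s1	CLCU	4
FLE-2	s1	GTCC	20
FLE-2	s1	SEND	50
FLE-3	s1	STAR	1
FLE-3	s1	AGLO	5
FLE-3	s1	CLCU	15
FLE-3	s1	SEND	16
FLE-4	s1	CULP	3
FLE-4	s1	CLCU	20
FLE-4	s1	GTCC	36
FLE-4	s1	SEND	60
FLE-5	s1	STAR	2
FLE-5	s1	ABSI	6
FLE-5	s1	CLCU	30
FLE-5	s1	SEND	90
FLE-6	s1	STAR	3
FLE-6	s1	LOAR	5
FLE-6	s1	CLCU	38
FLE-6	s1	SEND	74
FLE-7	s1	TSUI	40
FLE-7	s1	TIFI	50
FLE-7	s1	SEND	58
FLE-8	s1	STAR	2
FLE-8	s1	ABU	7
FLE-8	s1	CLCU	12
FLE-8	s1	SEND	67
PQE-1	s1	LIGHT	4
PQE-1	s1	STAR	6
PQE-1	s1	OA	10
PQE-1	s1	DUC	19
PQE-1	s1	GTCC	38
PQE-1	s1	SEND	83
PQE-2	s1	BLUV	5
PQE-2	s1	STAR	9
PQE-2	s1	OA	10
PQE-2	s1	GTCC	46
PQE-2	s1	SEND	68
PQE-3	s1	BUZZ	7
PQE-3	s1	STAR	12
PQE-3	s1	OA	10
PQE-3	s1	SEND	34
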