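subject_id	state	name	side	pi
TLE-4	ictal	STG	i	1.252
PQE-2	ictal	A	i	1.493
TLE-4	ictal	A	c	1.222
FLE-1	ictal	PHG	i	1.143
PQE-2	ictal	PHG	i	1.378
PQE-3	ictal	PHG	i	1.409
PQE-3	ictal	CingG	i	1.227
TLE-4	ictal	CingG	c	1.154
PQE-3	ictal	CingG	c	1.205
PQE-2	ictal	IFG	i	1.187
PQE-2	ictal	IFG	c	1.240
PQE-3	ictal	SPG	c	1.222
FLE-1	ictal	PrecG	i	1.126
TLE-3	ictal	PostG	i	1.237
FLE-1	ictal	Precuneus	i	1.247
TLE-3	ictal	Cuneus	i	1.188
TLE-4	ictal	Cuneus	i	1.162
FLE-8	ictal	Cuneus	i	1.224
TLE-4	ictal	Cuneus	c	1.403
TLE-4	ictal	LingG	i	1.172
TLE-3	ictal	SOG	i	1.249
FLE-1	ictal	SOG	i	1.259
PQE-2	ictal	SOG	i	1.507
FLE-1	ictal	IOG	c	1.180
FLE-1	ictal	MOFG	i	1.180
FLE-1	ictal	MOFG	c	1.236
PQE-2	ictal	MOFG	c	1.847
FLE-1	ictal	LOFG	c	1.121
PQE-2	ictal	LOFG	c	1.346
FLE-1	ictal	STRAG	i	1.379
FLE-8	ictal	STRAG	i	1.166
PQE-3	ictal	STRAG	i	1.368
FLE-1	ictal	STRAG	c	1.206
PQE-2	ictal	STRAG	c	1.530
PQE-3	ictal	STRAG	c	1.579
FLE-8	ictal	Entor	i	1.196
PQE-2	ictal	Entor	i	1.191
TLE-4	ictal	Entor	c	1.205
PQE-2	ictal	Entor	c	1.445
FLE-1	ictal	Insul	i	1.229
FLE-8	ictal	Insul	i	1.174
PQE-3	ictal	Insul	i	1.254
PQE-3	ictal	Insul	c	1.259
TLE-3	ictal	Cerebellum	c	1.176
TLE-3	ictal	RedN	c	1.592
TLE-4	ictal	RedN	c	1.205
TLE-3	ictal	SNig	c	1.333
TLE-3	ictal	CN	c	1.446
TLE-4	ictal	P	i	1.409
FLE-1	ictal	P	i	1.236
FLE-8	ictal	P	i	1.382
PQE-2	ictal	P	i	1.277
PQE-3	ictal	P	i	1.179
TLE-3	ictal	P	c	1.386
TLE-4	ictal	P	c	1.387
FLE-1	ictal	P	c	1.120
FLE-8	ictal	P	c	1.515
PQE-2	ictal	P	c	1.236
PQE-3	ictal	P	c	1.244
FLE-8	ictal	T	i	1.239
TLE-4	ictal	T	c	1.270
FLE-8	ictal	T	c	1.210
TLE-4	ictal	GP	i	1.364
FLE-8	ictal	GP	i	1.346
PQE-2	ictal	GP	i	1.356
TLE-3	ictal	GP	c	1.567
TLE-4	ictal	GP	c	1.325
FLE-8	ictal	GP	c	1.203
TLE-4	ictal	M	c	1.179
TLE-4	ictal	Pons	i	1.204
FLE-8	ictal	Pons	i	1.174
PQE-2	ictal	Pons	i	1.240
PQE-3	ictal	Pons	i	1.262
TLE-4	ictal	Pons	c	1.262
FLE-1	ictal	Pons	c	1.132
FLE-8	ictal	Pons	c	1.533
PQE-2	ictal	Pons	c	1.193
PQE-3	ictal	Pons	c	1.254
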