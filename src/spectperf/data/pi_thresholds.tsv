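subject_id	state	threshold
TLE-1	interictal	0.854
TLE-2	interictal	0.855
TLE-3	interictal	0.965
TLE-4	interictal	0.927
FLE-1	interictal	0.951
FLE-2	interictal	0.924
FLE-3	interictal	0.969
FLE-4	interictal	0.944
FLE-5	interictal	0.956
FLE-6	interictal	0.987
FLE-7	interictal	0.975
FLE-8	interictal	0.883
PQE-1	interictal	0.950
PQE-2	interictal	0.917
PQE-3	interictal	0.950
TLE-3	ictal	1.171
TLE-4	ictal	1.148
FLE-1	ictal	1.118
FLE-2	ictal	1.114
FLE-8	ictal	1.142
PQE-2	ictal	1.155
PQE-3	ictal	1.154
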