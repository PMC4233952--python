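sample_ref	age	sex	joint_status	mankin_score
N_M18	18	M	non-OA	3
N_M15	15	M	non-OA	0
N_M14	14	M	non-OA	1
N_F24	24	F	non-OA	1
N_M21	21	M	non-OA	3
N_F37	37	F	non-OA	2
N_F16	16	F	non-OA	1
I_M63	63	M	OA	6
I_M80	80	M	OA	8
I_F68	68	F	OA	5
I_F78	78	F	OA	9
I_F72	72	F	OA	4
I_M66	66	M	OA	4
F_M73	73	M	OA	15
F_M61	61	M	OA	12
F_M74	74	M	OA	21
F_M60	60	M	OA	17
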