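name	spec	aa_deleted	tail_length_nm	tail_note	eop	eop_censored	plaque_morphology	lysogeny_frequency	lysogeny_censored	fl_with_tails	convention_note
WT		0	118		1	False	Clear, 1.5 mm	4.4e-3	False	4.8e-3
D1-2	R1..2	29	109.5		4.5	False	Clear, 1.5 mm	3.8e-3	False
D1-3	R1..3	40			6.8e-2	False	0.75 mm	1.4e-3	False
D1-4	R1..4	51			1.5e-8	True	NA	9.0e-5	False
D1-5	R1..5	69			3	False	Clear, 1 mm	1.8e-3	False
D1-7.5	R1..7+half	100	101		1.5e-8	True	NA	1.1e-4	False	2.3e-3
D1-8	R1..8	109			3	False	0.75 mm	5.3e-3	False
D1-9	R1..9	120	98		0.88	False	Clear, 1 mm	4.5e-3	False
D1-10	R1..10	131			6.8e-4	False	0.5 mm	3.5e-3	False
D1-12	R1..12	153			6	False	Clear, 1.5 mm	1.9e-3	False
D1-15	R1..15	186			5.4	False	Clear, 1.5 mm	2.6e-3	False
D1-18	R1..18	219			1.4	False	Clear, 1.5 mm	7.6e-3	False
D1-29	R1..29	347	65		1.5e-8	True	NA	1.6e-5	False	6.5e-4
D20-26	R20..26	84			6.5	False	Clear, 1.5 mm	2.2e-3	False
D24-26	R24..26	40			4.3	False	Clear, 1.5 mm	2.4e-3	False
D24-29	R24..29	73			2.0e-3	False	Fuzzy, 1 mm	3.5e-3	False
D1-5,24-26	R1..5;R24..26	109			0.6	False	0.5 mm	4.2e-3	False
D1-9,24-26	R1..9;R24..26	160			8.2e-3	False	0.5 mm	1.7e-3	False
D1-9,20-26	R1..9;R20..26	204	86.7		0.34	False	0.5 mm	2.4e-3	False
D1-9,24-29	R1..9;R24..29	193			1.5e-8	True	NA	4.3e-5	False	3.5e-3
D1-9,20-29	R1..9;R20..29	237			1.5e-8	True	NA	1e-4	False	2.1e-3
D1-12,20-29	R1..12;R20..29	270	77		1.5e-8	True	NA	4.6e-4	False	1.0e-3
D1-15,20-29	R1..15;R20..29	303			1.5e-8	True	NA	3.4e-4	False	1.5e-3
D1-18,20-29	R1..18;R20..29	336			1.5e-8	True	NA	3.4e-4	False
DTM1-3	tm1..3	71			1.5e-8	True	NA	1.5e-8	True	2.8e-3
DTM3	tm3..3	19			1.5e-8	True	NA	3.2e-4	False	2.0e-3
DTM2-3	tm2..3	43	107.6		1.5e-8	True	NA	1.3e-7	False	2.6e-3
DTM4-6	tm4..6	89			6.8e-2	False	NA	4.4e-3	False
DTM1-6	tm1..6	160		No tails	1.5e-8	True	NA	1.5e-8	True	4.0e-3
DTM4	tm4..4	23			3.4	False	Clear, 1.5 mm	8.9e-4	False
DE2-F31	res2..31	30		No tails	1.5e-8	True	NA	1.5e-8	True	3.1e-3
DT908-F937	res908..937	30		No tails	1.5e-8	True	Clear, 1.5 mm	1.5e-8	True	2.7e-3
DF810-G842	res810..842	33			9.5e-7	False	pinpoint	4.4e-4	False
DL843-V875	res843..875	33			1.4e-5	False	pinpoint	7.4e-5	False
DF810-V875	res810..875	66			2.0e-6	False	pinpoint	5.4e-5	False
D1-29,F810-G842	R1..29;res810..842	380			1.5e-8	True	NA	4.1e-5	False	2.8e-3
D1-29,F810-V875	R1..29;res810..875	413			1.5e-8	True	NA	3.4e-6	False	1.9e-3
D1-29,F810-T908	R1..29;res810..908	446		No tails	1.5e-8	True	NA	1.5e-8	True	3.5e-3
DF31-I61	res31..61	30			1.5e-8	True	NA	1.5e-8	True	6.0e-4	f31_retained
DF31-L141	res31..141	110		No tails	1.5e-8	True	NA	1.5e-8	True	5.8e-4	f31_retained
DI62-L141	res62..141	80			1.5e-8	True	NA	1.5e-8	True	3.4e-3
DA142-E154	res142..154	13			1.5e-8	True	NA	1.5e-8	True	2.2e-3
DI62-L141,1-29,F810-T908	res62..141;R1..29;res810..908	526			1.5e-8	True	NA	1.5e-8	True	2.6e-3
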