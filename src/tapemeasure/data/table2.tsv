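name	spec	aa_deleted	phage_morphology	eop	eop_censored	reduced_plaque	lysogeny_frequency
WT		0	Intact	1	False	False	4.6e-4
D1-3.1	R1..3+1	41	Heads only	3.0e-7	True	False	2.5e-4
D1-3.2	R1..3+2	42	Heads only	3.0e-7	True	False	6.5e-4
D1-3.3	R1..3+3	43	Intact	4.0	False	True	2.4e-3
D1-3.4	R1..3+4	44	Intact	3.0e-7	True	False	2.1e-4
D1-3.5	R1..3+5	45	Heads only	3.0e-7	True	False	8.8e-4
D1-3.6	R1..3+6	46	Heads only	3.0e-7	True	False	6.5e-4
D1-3.7	R1..3+7	47	Intact	6.8	False	True	6.7e-4
D1-3.8	R1..3+8	48	Heads only	3.0e-7	True	False	5.5e-4
D1-3.9	R1..3+9	49	Intact	3.0e-7	True	False	6.3e-4
D1-3.10	R1..3+10	50	Intact	0.8	False	True	5.4e-4
D1-3.11	R1..3+11	51	Intact	3.0e-7	True	False	9.0e-5
D4::Ala6	R4::AAAAAA	NA	ND	0.08	False	False	1.7e-4
D4::Ala11	R4::AAAAAAAAAAA	NA	ND	0.06	False	False	1.5e-4
D3-3.5	R3..3+5	16	Heads, long tails	3.0e-7	True	False	7.3e-4
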