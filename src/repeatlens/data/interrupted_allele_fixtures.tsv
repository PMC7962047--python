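# Literature interruption patterns for the DM1 families analysed here.
# n_value fixes any literal "n" in the pattern; it is configuration chosen to
# land near the observed repeat-size modes, not ground truth.
# expected_interruptions: semicolon-separated MOTIF:units, "-" for pure tracts.
label	pattern	n_value	expected_total_units	expected_interruptions	localization
G2.1	(CTG)6(CCGCTG)13(CTG)5	-	37	CCG:13	internal
G2.2	(CTG)6(CCGCTG)13(CTG)5	-	37	CCG:13	internal
G2.3	(CTG)6(CCGCTG)13(CTG)5	-	37	CCG:13	internal
G2.4	(CTG)6(CCGCTG)13(CTG)5	-	37	CCG:13	internal
G3.1	(CTG)6(CCGCTG)13(CTG)5	-	37	CCG:13	internal
G3.2	(CTG)6(CCGCTG)13(CTG)5	-	37	CCG:13	internal
G4.1	(CTG)6(CCGCTG)13(CTG)5	-	37	CCG:13	internal
E1	(CTG)n	440	440	-	pure
E2.1	(CTG)n(CCGCTG)(CTG)7(CCGCTG)(CTG)11	350	372	CCG:2	3'
E3	(CTG)n(CCGCTG)2(CTG)3(CCGCTG)2(CTG)5(CCGCTG)(CTG)7(CCGCTG)(CTG)11	140	178	CCG:6	3'
A4.1	(CTG)20(CAG)1(CTG)100	-	121	CAG:1	5'
B2	(CTG)11(CCGCTG)(CTG)1(CCGCTG)(CTG)3(CCGCTG)(CTG)n	280	301	CCG:3	5'
L2	(CTG)n	957	957	-	pure
L3	(CTG)n	1156	1156	-	pure
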