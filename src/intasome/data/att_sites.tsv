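# Default att-site registry for the lambda recombination toolkit.
# Coordinate system: integer bp positions on the top strand, origin at the
# center base pair of the 7-bp overlap, P arm negative, P' arm positive;
# intervals are closed/inclusive.  B and B' are attB-side bookkeeping records
# on their own (attB) coordinate line, with flanks given below.
# Exact coordinates are a modeling default chosen to satisfy the documented
# constraints (240 bp total, 7-bp overlap, site ordering); they are not
# experimental ground truth.
#att_length	240
#p_arm	-130	-4
#pprime_arm	4	79
#b_flank	-18	-4
#bprime_flank	4	18
name	category	arm	start	end
P1	arm	P	-130	-120
H1	ihf	P	-116	-98
P2	arm	P	-94	-84
X2	xis	P	-81	-69
F	fis	P	-81	-69
X1.5	xis	P	-68	-60
X1	xis	P	-59	-49
H2	ihf	P	-45	-25
C	core	core	-10	-4
O	overlap	core	-3	3
C'	core	core	4	10
H'	ihf	P'	14	33
P'1	arm	P'	36	46
P'2	arm	P'	47	57
P'3	arm	P'	58	68
B	core	core	-11	-4
B'	core	core	4	11
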