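operator_id	name	smirks	ec3	cofactor_reactants	cofactor_products
bro01	alcohol_oxidation	[C;!$(C=O):1][OX2H1:2]>>[C:1]=[O:2]	1.1.1	nad_ox	nad_red
bro02	carbonyl_reduction	[C;!$(C(=O)[OX2H1,OX1,N]):1](=[O:2])>>[C:1][OX2H1:2]	1.1.1	nad_red	nad_ox
bro03	decarboxylation	[#6;!$(C=O):1][CX3](=O)[OX2H1]>>[#6:1]	4.1.1		co2
bro04	dehydration	[CX4:1]([OX2H1])[CX4!H0:2]>>[C:1]=[C:2]	4.2.1		h2o
bro05	hydration	[CX3;!$(C=O):1]=[CX3;!$(C=O):2]>>[C:1]([OX2H1])[C:2]	4.2.1	h2o
bro06	reductive_amination	[C;!$(C(=O)[O,N]):1]=[O:2]>>[C:1][NX3H2]	1.4.1	nh3;nad_red	h2o;nad_ox
bro07	phosphorylation	[CX4:1][OX2H1:2]>>[C:1][O:2]P(=O)(O)O	2.7.1	atp	adp
bro08	o_methylation	[CX4:1][OX2H1:2]>>[C:1][O:2]C	2.1.1	sam	sah
bro09	carboxylation	[CX4!H0:1]>>[C:1]C(=O)[OX2H1]	6.4.1	co2
bro10	enoate_reduction	[CX3;!$(C=O):1]=[CX3;!$(C=O):2]>>[C:1][C:2]	1.3.1	nad_red	nad_ox
bro11	desaturation	[CX4!H0:1][CX4!H0:2]>>[C:1]=[C:2]	1.3.1	nad_ox	nad_red
bro12	alcohol_amination	[CX4:1][OX2H1:2]>>[C:1][NX3H2]	2.6.1	nh3	h2o
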