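mirna	target_gene	align_score	tpb	category	annotation
miRC2	ppa010261m	5	751.0	2	Zinc finger protein
miRC3	ppb024266m	3.5	350.5	2	NBS-LRR class disease resistance protein
miRC4	ppa012465m	4.5	10263.4	2	Unknown protein
miRC5	ppb024266m	5	350.5	2	NBS-LRR class disease resistance protein
miRC6a	ppa019098m	4	40.1	2	Pentatricopeptide (PPR) repeat-containing protein
miRC6a	ppa020475m	1	5997.8	0	Pentatricopeptide (PPR) repeat-containing protein
miRC6a	ppa023796m	5	15.0	4	Pentatricopeptide (PPR) repeat-containing protein
miRC6b	ppa019098m	4.5	40.1	2	Pentatricopeptide (PPR) repeat-containing protein
miRC6b	ppa020475m	1.5	5997.8	0	Pentatricopeptide (PPR) repeat-containing protein
miRC12	ppa000294m	5	600.8	2	Protein kinase family protein
miRC12	ppa000823m	5	851.1	2	Translation initiation factor
miRC13	ppa008890m	5	2353.1	2	Esterase/lipase/thioesterase family protein
miRC13	ppa010397m	4.5	100.1	3	Allene-oxide cyclase
miRC16	ppa018545m	5	100.1	3	FAR1-related sequence 3; zinc ion binding
miRC16	ppa022612m	5	100.1	3	FAR1-related sequence 3; zinc ion binding
miRC29	ppa002618m	5	50.1	3	RNA binding / translation initiation factor
miRC29	ppa002620m	5	50.1	3	RNA binding / translation initiation factor
miRC30	ppa004763m	4.5	25.0	4	Catalase
miRC45	ppa002666m	5	1552.0	2	Vernalization independence; DNA binding
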