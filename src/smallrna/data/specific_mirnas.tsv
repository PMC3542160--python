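mirna	sequence	length	scaffold	match_site	strand	rpm_root	rpm_leaf	rpm_flower	rpm_fruit	rpm_total	star_sequence
miRC1	ACCUGGCUCUGAUACCAUAAC	21	Scaffold_3	8575480	+	1571	908	13139	7818	23436	CGUGGUAUCAGAGUCAUGUUA
miRC2	UGAAGGAAGAUUUGUGGAAAG	21	Scaffold_7	18921374	-	1573	3962	117	53	5705	UUCCACAGAUCUUUCCUCAUU
miRC3	CUUCCCAAACCUCCCAUUCCUA	22	Scaffold_1	29648613	+	40	33	1288	2804	4165	GGAAUGGGAGGAUUGGGAAAA
miRC4	UGAGCAAUGGCACACAGCCCU	21	Scaffold_3	2185580	+	0	0	1273	1837	3110	UUGUGCCAUUGCUCAAGC
miRC5	UUUCCGAAACCUCCCAUUCCAA	22	Scaffold_1	29646139	+	60	3	515	2080	2658	GGGUGAGAGGUUGCCGGAAAGA
miRC6a	UUAUACAAUGAAAUCACGGCCG	22	Scaffold_1	2254120	+	1286	309	249	328	2172	GCCGUGUUUCUUUGUAUAAAG
miRC6b	UUAUACAAUGAAAUCACGGUCG	22	Scaffold_1	2244523	+	97	15	58	10	180	CCGUGUUUCCUUGUAUAAAG
miRC7	UGGCACCAAUGAUACCAAGUUU	22	Scaffold_7	18801272	-	0	0	986	404	1390	ACUUGGUAUCUUGGUGCCGGU
miRC8	CAGGAAAGAAUGUGAUGAGUA	21	Scaffold_2	2899303	+	24	469	11	0	504	UUUGCUCGUCACAUUCUUUCC
miRC9	UCGCAGGAGAGAUGGCACUGUC	22	Scaffold_3	19986823	-	109	16	0	0	125	UGGUGUCAUCCCUCCUGUGACC
miRC10	CGAACUUAUUGCAACUAGCUU	21	Scaffold_4	6342241	+	3	19	0	56	78	GCUAGGUGCAACAAGUUCAAU
miRC11	GGAGCGACCUGGGAUCACAUG	21	Scaffold_4	23714205	+	12	14	1	22	49	UGUGUUCUCAGGUCGCCCCUG
miRC12	UCUGAGUCAGAUUACUGAAUA	21	Scaffold_6	8360495	+	10	32	1	0	43	UUCAGUAUUUUGACUCAGAA
miRC13	ACUCUCCCUCAAAGGCUUCUAG	22	Scaffold_5	11892663	+	7	14	4	12	37	CGAAGCCUUUGGGGAGAGUAA
miRC14	UAGAGAGAUGGUCAGCAAUGU	21	Scaffold_4	14225624	+	3	3	1	26	33	AUUGCUGAUCACCUCUCUAAU
miRC15	CCACAUUUAUAGAUUACCUUG	21	Scaffold_7	10402743	-	0	0	9	20	29	CAAGGUAGUUUAUAAAUGUGG
miRC16	UUCAAAGGGUACAUCCACAGU	21	Scaffold_2	18505840	+	0	5	8	9	22	CAACUGUGGACAUACCCUUUG
miRC17	UCUGUCGUAGGAGAGAUGGCGC	22	Scaffold_3	19984391	-	9	0	0	12	21	UCAUCUCUCCUCGACUGAA
miRC18	UCGUGGGGAGAGAUCUAAUCG	21	Scaffold_7	18333173	-	0	0	6	12	18	AUUAGACCUCUCCCGACGAAA
miRC19	CCUCCCAUGCCACGCAUUUCUA	22	Scaffold_8	10608407	-	0	0	11	6	17	GAGAUGGGUGGCUGGGAAGGA
miRC20	AUUUCGACUAAUAACACAAUG	21	Scaffold_7	1039113	+	3	0	2	11	16	UUGUGUUAUUGGCCGAAAAUAG
miRC21	AUAAUAAUGUCCGGAUGUCAA	21	Scaffold_6	19901315	+	0	11	0	0	11	GAUAUCCGCACAUUAUUAUUG
miRC22	CCCUUCCAGUAAGGCACCCCC	21	Scaffold_5	13061652	+	0	0	1	10	11	GGGUUCCUUGUUGGAAGGACU
miRC23	AUUUCAGCUAAGUUGAGUUGU	21	Scaffold_3	13433851	+	0	1	8	1	10	AAUCAACUCAGCUUAGCUGAACUG
miRC24	UCCCUCAAGGGCUCCCAAUAUU	22	Scaffold_3	9747805	-	2	0	0	8	10	UGUUGGGGGCUCUUUUG
miRC25	UCAAUUAGAAAAUGAUAAGUG	21	Scaffold_6	7122989	+	0	0	5	2	7	CUUGUUAUUUUUUAAUUGAUU
miRC26	UCCAACGAUGGGUGACCACAA	21	Scaffold_7	16562805	-	0	0	2	5	7	UUUGUGGUCAUUCACCGUUGGA
miRC27	UCCUGUGCGAACGUCCAGAAG	21	Scaffold_1	498129	+	3	4	0	0	7	UAACUUCCGAACGUCCGCAUA
miRC28	CUUGUUAUUUUUUAAUUGAUU	21	Scaffold_6	9969911	-	0	0	4	1	5	AACCAAUUAGAAAAUAACAAGUGG
miRC29	AAAGACUAAAAUACCCUUGA	20	Scaffold_5	6250039	-	8	6	45	1	60	None detected
miRC30	UACUUGACCCCACAACUGGUU	21	Scaffold_1	27613921	+	1	6	13	24	44	None detected
miRC31	UGGGCACGCCAGAAUAAAGCAA	22	Scaffold_7	13727378	+	12	27	0	0	39	None detected
miRC32	UAAGGUUGAGCCGGAAAUCGGA	22	Scaffold_6	8366918	+	2	3	2	19	26	None detected
miRC33	CUCUUAAUCGUUGGAUCAAAUU	22	Scaffold_5	10113319	-	0	0	0	22	22	None detected
miRC34	UGCUUGUUGAGAUGUGCGGUU	21	Scaffold_8	6836158	+	17	1	0	1	19	None detected
miRC35	UGUGUUAAUCGUAGAAAAUAU	21	Scaffold_1	27061839	+	6	2	8	1	17	None detected
miRC36	AAUGUCACCUCCCACACUCCU	21	Scaffold_4	23445268	+	0	0	0	16	16	None detected
miRC37	UGGACGUCUAGAAAAAUACGG	21	Scaffold_4	23035470	+	7	8	0	0	15	None detected
miRC38	UUAAGCCCAAGAAAGCCCGAC	21	Scaffold_4	23839384	+	0	0	0	14	14	None detected
miRC39	ACCUCUUAUAGAUAGUCCCCA	21	Scaffold_3	193497	+	0	0	0	12	12	None detected
miRC40	AGACAGGUUCUUUUAUCUCAUG	22	Scaffold_1	22425519	-	0	0	3	9	12	None detected
miRC41	UCGAUUUUAUGUUUUAAGUAUC	22	Scaffold_4	22126310	+	0	0	6	5	11	None detected
miRC42	UCUGACUUUUACCAGAAUCUGA	22	Scaffold_5	11020912	+	3	0	0	5	8	None detected
miRC43	CAUUAGAGCGGUGGUACACAA	21	Scaffold_1	30892686	+	1	4	2	0	7	None detected
miRC44	UGCCAAGAAAGAGUUGCCCUA	21	Scaffold_3	1327042	-	0	3	2	0	5	None detected
miRC45	ACCUCCUCAUUCUAACCCCUCA	22	Scaffold_1	29656462	-	0	0	0	4	4	None detected
miRC46	UGCAUGCACCUUGAUAGAUGU	21	Scaffold_5	17169215	-	0	0	0	4	4	None detected
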