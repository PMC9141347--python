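species	assembly_length	te_covered	te_percent	main_family
Ascogregarina_taiwanensis	6149411	97453	1.58	LTR_Gypsy_like
Babesia_bigemina	13840936	133787	0.97	LINE_like
Babesia_divergens	9725408	41125	0.42	LINE_like
Babesia_ovata	14453397	77825	0.54	LINE_like
Cyclospora_cayetanensis	44363576	2176795	4.91	LTR_Gypsy_like
Cystoisospora_suis	83637532	1169252	1.40	LTR_Gypsy_like
Eimeria_acervulina	45830609	783904	1.71	LTR_Gypsy_like
Eimeria_brunetti	66890165	1567917	2.34	LTR_Gypsy_like
Eimeria_falciformis	43671268	256248	0.59	LTR_Gypsy_like
Eimeria_maxima	45975062	470783	1.02	LTR_Gypsy_like
Eimeria_mitis	72240319	1298206	1.80	LTR_Gypsy_like
Eimeria_necatrix	55007932	920585	1.67	LTR_Gypsy_like
Eimeria_nieschulzi	62832469	2365007	3.76	LTR_Gypsy_like
Eimeria_praecox	60083328	1423429	2.37	LTR_Gypsy_like
Eimeria_tenella	51859607	637259	1.23	LTR_Gypsy_like
Gregarina_niphandrodes	14009070	432988	3.09	LTR_Gypsy_like
Haemoproteus_tartakovskyi	23209007	12683	0.05	LTR_Gypsy_like
Plasmodium_gallinaceum	25034007	1351686	5.40	LTR_Gypsy_like
Plasmodium_relictum	22607426	1105627	4.89	LTR_Gypsy_like
Theileria_equi	11674479	101054	0.87	LINE_like
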