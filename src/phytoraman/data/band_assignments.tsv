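label	center	mode	molecule_class
carbohydrate_479	479	d(C-C-C)	carbohydrate
phospholipid_865	865	vs(O-C-C-N) C4N+	phospholipid
chlorophyll_988	988	d(CH3)	chlorophyll
carotenoid_1157	1157	v(C-C)	carotenoid
carotenoid_1524	1524	v(C=C)	carotenoid
lipid_1444	1444	d(CH2) scissoring	lipid
lipid_1660	1660	v(C=C) cis	lipid
lipid_1750	1750	v(C=O)	lipid
lipid_2850	2850	v(CH2)	lipid
lipid_2885	2885	v(CH3)	lipid
lipid_2940	2940	vas(CH2)	lipid
lipid_2970	2970	v(CH3)	lipid
lipid_3008	3008	vas(=C-H)	lipid
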