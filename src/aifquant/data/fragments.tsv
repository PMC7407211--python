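name	ion_composition	neutral_loss	class_tag	comment
glycinate	C2H4NO2		glycine-conjugate	deprotonated glycine, m/z 74.0248
taurine SO3-	O3S		taurine-conjugate	m/z 79.9574
taurine vinylsulfonate	C2H3O3S		taurine-conjugate	m/z 106.9808
taurate	C2H6NO3S		taurine-conjugate	deprotonated taurine, m/z 124.0074
bisulfate	HO4S		sulfate	m/z 96.9601
SO3 neutral loss		O3S	sulfate	computed 79.9568 Da; sometimes quoted as 79.9597
glucuronide	C6H9O7		glucuronide	dehydrated glucuronate, m/z 193.0354
demethylated phosphocholine	C4H11NO4P		LPL-headgroup-PC	m/z 168.0431
glycerophosphoethanolamine	C2H7NO4P		LPL-headgroup-PE	m/z 140.0118
inositol cyclic phosphate	C6H10O8P		LPL-headgroup-PI	m/z 241.0119
glycerophosphate	C3H6O5P		LPL-headgroup-PS	m/z 152.9958, after serine loss
glycerophosphate	C3H6O5P		LPL-headgroup-PG	m/z 152.9958
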