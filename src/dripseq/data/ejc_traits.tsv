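species	family	saccharomycotina	MAGO	Y14	UPF3	PYM	ALYREF	IBP160
Cryptococcus_neoformans	Basidiomycota	no	+	+	+	+	+	+
Ustilago_maydis	Basidiomycota	no	+	+	+	+	+	+
Schizosaccharomyces_pombe	Taphrinomycotina	no	+	+	+	+	+	+
Taphrina_deformans	Taphrinomycotina	no	+	+	+	+	+	+
Neurospora_crassa	Pezizomycotina	no	+	+	+	+	+	+
Aspergillus_nidulans	Pezizomycotina	no	+	+	+	+	+	+
Yarrowia_lipolytica	Yarrowiaceae	yes	+	+	+	+	+	+
Candida_hispaniensis	Yarrowiaceae	yes	+	+	+	+	+	+
Geotrichum_candidum	Yarrowiaceae	yes	+	+	+	+	+	+
Blastobotrys_adeninivorans	Trichomonascaceae	yes	+	+	+	+	+	+
Sugiyamaella_lignohabitans	Trichomonascaceae	yes	+	+	+	+	+	+
Candida_albicans	CTG	yes	-	-	+	-	-	-
Debaryomyces_hansenii	CTG	yes	-	-	+	-	-	-
Scheffersomyces_stipitis	CTG	yes	-	-	+	-	-	-
Komagataella_phaffii	Pichiaceae	yes	-	-	+	-	+	-
Ogataea_polymorpha	Pichiaceae	yes	-	-	+	-	+	-
Cyberlindnera_fabianii	Phaffomycetaceae	yes	+	+	+	+	+	+
Wickerhamomyces_ciferrii	Phaffomycetaceae	yes	+	+	+	+	+	+
Saccharomyces_cerevisiae	Saccharomycetaceae	yes	-	-	+	-	-	-
Candida_glabrata	Saccharomycetaceae	yes	-	-	+	-	-	-
Kluyveromyces_lactis	Saccharomycetaceae	yes	-	-	+	-	-	-
Zygosaccharomyces_rouxii	Saccharomycetaceae	yes	-	-	+	-	-	-
Lachancea_thermotolerans	Saccharomycetaceae	yes	-	-	+	-	-	-
Eremothecium_gossypii	Saccharomycetaceae	yes	-	-	+	-	-	-
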