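((Cryptococcus_neoformans,Ustilago_maydis),((Schizosaccharomyces_pombe,Taphrina_deformans),((Neurospora_crassa,Aspergillus_nidulans),(((Yarrowia_lipolytica,Candida_hispaniensis),(Geotrichum_candidum,(Blastobotrys_adeninivorans,Sugiyamaella_lignohabitans))),(((Candida_albicans,(Debaryomyces_hansenii,Scheffersomyces_stipitis)),(Komagataella_phaffii,Ogataea_polymorpha)),((Cyberlindnera_fabianii,Wickerhamomyces_ciferrii),(Saccharomyces_cerevisiae,(Candida_glabrata,(Kluyveromyces_lactis,(Zygosaccharomyces_rouxii,(Lachancea_thermotolerans,Eremothecium_gossypii)))))))))));
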