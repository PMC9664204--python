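((sea_lamprey,((elephant_shark,((spotted_catshark,whale_shark)Selachii,thorny_skate)Elasmobranchii)Chondrichthyes,(((reedfish,bichir)Polypteridae,(spotted_gar,(european_eel,(asian_bonytongue,(zebrafish,((northern_pike,atlantic_salmon)Protacanthopterygii,(atlantic_cod,medaka)Acanthomorpha)Euteleostei)Clupeocephala)Osteoglossocephalai)Teleostei)Neopterygii)Actinopterygii,(coelacanth,(((xenopus_tropicalis,xenopus_laevis)Xenopus,leishan_spiny_toad)Amphibia,((platypus,(opossum,human)Theria)Mammalia,(green_anole,(chicken,duck)Aves)Sauropsida)Amniota)Tetrapoda)Sarcopterygii)Osteichthyes)Gnathostomata)Vertebrata)Vertebrata_1R;
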