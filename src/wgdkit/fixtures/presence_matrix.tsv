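subtype	sea_lamprey	elephant_shark	spotted_catshark	whale_shark	thorny_skate	reedfish	bichir	spotted_gar	european_eel	asian_bonytongue	zebrafish	atlantic_cod	medaka	northern_pike	atlantic_salmon	coelacanth	xenopus_tropicalis	xenopus_laevis	leishan_spiny_toad	platypus	opossum	human	green_anole	chicken	duck
TRPV1	?	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
TRPV2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	1	1
TRPV3	0	1	1	1	1	0	0	0	0	0	0	0	0	0	0	1	1	1	1	1	1	1	1	1	1
TRPV4	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
TRPV5	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1	1
TRPV7	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	1	1	1	1	1	0	0	0	0	0
TRPV8	1	1	1	1	1	1	1	0	0	0	0	0	0	0	0	1	1	1	1	1	P	0	0	0	0
TRPV9	0	0	1	1	1	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0
sauTRPV5-2	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	0	1	P	P
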