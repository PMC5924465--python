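species_a	species_b	bd	same_order	published_bdn
Coeloplana_loyai	Coeloplana_yulianicorum	0	1	0.00
Coeloplana_loyai	Vallicula_multiformis	5	1	0.38
Coeloplana_loyai	Mnemiopsis_leidyi	9	0	0.69
Coeloplana_loyai	Pleurobrachia_bachei	11	0	0.85
Coeloplana_yulianicorum	Vallicula_multiformis	5	1	0.38
Coeloplana_yulianicorum	Mnemiopsis_leidyi	9	0	0.69
Coeloplana_yulianicorum	Pleurobrachia_bachei	11	0	0.85
Vallicula_multiformis	Mnemiopsis_leidyi	11	0	0.85
Vallicula_multiformis	Pleurobrachia_bachei	12	0	0.77
Mnemiopsis_leidyi	Pleurobrachia_bachei	12	0	0.92
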