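species	genome_length	nc_with_urfs	nc_without_urfs	n_nc_gt20_with	n_nc_gt20_without	longest_nc_with	longest_nc_with_location	longest_nc_without	longest_nc_without_location
Coeloplana_loyai	11574	930	132	4	2	687	nad2-rnl	59	nad6-cox1
Coeloplana_yulianicorum	11551	908	90	5	1	318	nad2-rnl	41	nad6-cox1
Vallicula_multiformis	9961	119	25	1	0	94	nad1-nad6	13	nad6-cox1
Mnemiopsis_leidyi	10326	406	265	3	2	276	nad6-cox1	132	nad6-urf1
Pleurobrachia_bachei	11016	755	429	8	5	276	cox2-rns	161	nad4-cob
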