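otu	cluster_name	cluster_n	n_seqs	n_classes	n_orders	n_families	n_genus	n_species	host_a	host_b	max_age_my
Badnavirus	Badnavirus-01	20	75	2	9	10	12	12	Dioscorea	Amborella	191
Badnavirus	Badnavirus-02	43	5	1	2	2	2	2	Phalaenopsis	Musa	117
Caulimovirus	Caulimovirus-01	28	36	1	3	3	5	8	Helianthus	Arabidopsis	118
Caulimovirus	Caulimovirus-02	52	2	1	1	1	1	1	Gossypium	Gossypium	0
Dioscovirus	Dioscovirus-01	23	49	1	3	3	4	5	Cynara	Cajanus	118
Dioscovirus	Dioscovirus-02	25	43	1	1	1	1	2	Dioscorea	Dioscorea	0
Dioscovirus	Dioscovirus-03	31	24	1	1	1	2	2	Glycine	Vigna	23
Dioscovirus	Dioscovirus-04	34	16	1	1	1	1	1	Macadamia	Macadamia	0
Dioscovirus	Dioscovirus-05	35	12	1	1	1	1	2	Dioscorea	Dioscorea	0
Petuvirus	Petuvirus-01	1	1202	1	5	5	10	19	Arachis	Citrus	108
Petuvirus	Petuvirus-02	14	131	1	9	9	16	18	Amborella	Helianthus	191
Petuvirus	Petuvirus-03	15	129	1	3	4	6	9	Coffea	Gossypium	118
Petuvirus	Petuvirus-04	19	78	1	1	1	11	13	Brassica	Rorippa	27
Petuvirus	Petuvirus-05	22	52	1	1	1	1	1	Ipomoea	Ipomoea	0
Petuvirus	Petuvirus-06	27	39	1	1	1	7	9	Arachis	Cicer	59
Petuvirus	Petuvirus-07	30	24	1	3	3	4	6	Populus	Gossypium	108
Petuvirus	Petuvirus-08	33	18	1	1	1	3	8	Citrus	Atalantia	18
Petuvirus	Petuvirus-09	36	12	1	2	2	2	2	Durio	Macadamia	123
Petuvirus	Petuvirus-10	39	8	1	1	1	1	1	Eucalyptus	Eucalyptus	0
Solendovirus	Solendovirus-01	3	1124	1	2	2	5	8	Nymphaea	Nicotiana	179
Soymovirus	Soymovirus-01	6	391	1	1	1	1	3	Arachis	Arachis	0
Soymovirus	Soymovirus-02	24	49	1	4	5	6	6	Lactuca	Cleome	118
Soymovirus	Soymovirus-03	42	6	1	1	1	1	1	Chenopodium	Chenopodium	0
Soymovirus	Soymovirus-04	44	5	1	1	1	3	3	Brassica	Cakile	13
Soymovirus	Soymovirus-05	48	3	1	1	1	1	1	Medicago	Medicago	0
Tungrovirus	Tungrovirus-01	8	251	1	3	3	10	29	Prunus	Vitis	117
Tungrovirus	Tungrovirus-02	29	32	1	1	1	1	1	Lindenbergia	Lindenbergia	0
Tungrovirus	Tungrovirus-03	38	9	1	1	1	1	1	Cinnamomum	Cinnamomum	0
Tungrovirus	Tungrovirus-04	46	4	1	1	1	1	2	Malus	Malus	0
Tungrovirus	Tungrovirus-05	54	2	1	1	1	1	1	Citrus	Citrus	0
Florendovirus	Florendovirus-01	0	3207	2	27	34	70	114	Asparagus	Amborella	191
Florendovirus	Florendovirus-02	2	1188	1	6	8	21	35	Brassica	Nicotiana	118
Florendovirus	Florendovirus-03	4	949	2	21	27	38	47	Asparagus	Amborella	191
Florendovirus	Florendovirus-04	7	317	1	2	2	2	3	Coffea	Lindenbergia	77
Florendovirus	Florendovirus-05	12	133	1	1	1	3	5	Arachis	Lotus	59
Florendovirus	Florendovirus-06	13	132	1	2	2	5	8	Lindenbergia	Nicotiana	79
Florendovirus	Florendovirus-07	16	120	1	8	9	13	18	Amborella	Brassica	191
Florendovirus	Florendovirus-08	18	79	1	2	2	7	8	Glycine	Manihot	101
Florendovirus	Florendovirus-09	41	7	1	1	2	2	2	Capsicum	Nicotiana	24
Florendovirus	Florendovirus-10	47	4	1	1	1	2	2	Cucumis	Momordica	48
Florendovirus	Florendovirus-11	51	2	2	2	2	2	2	Asparagus	Prunus	160
Gymnendovirus	Gymnendovirus-1-1	17	95	1	1	1	2	2	Pinus	Picea	130
Wendovirus	Wendovirus-01	9	200	1	1	1	4	11	Citrus	Atalantia	18
Wendovirus	Wendovirus-02	21	70	1	2	2	3	3	Helianthus	Coffea	101
Wendovirus	Wendovirus-03	40	7	1	2	2	3	4	Citrus	Solanum	118
Wendovirus	Wendovirus-04	49	3	1	1	1	1	1	Lindenbergia	Lindenbergia	0
Wendovirus	Wendovirus-05	55	1	1	1	1	1	1	Olea	Olea	0
Wendovirus	Wendovirus-06	56	1	1	1	1	1	1	Portulaca	Portulaca	0
Xendovirus	Xendovirus-01	26	41	1	4	4	6	8	Vaccinium	Rosa	118
Xendovirus	Xendovirus-02	32	19	1	1	1	1	1	Olea	Olea	0
Xendovirus	Xendovirus-03	45	5	1	1	1	1	1	Ipomoea	Ipomoea	0
Yendovirus	Yendovirus-01	10	190	1	1	1	9	11	Oryza	Eleusine	47
Yendovirus	Yendovirus-02	11	142	2	5	5	8	12	Dioscorea	Solanum	160
Yendovirus	Yendovirus-03	50	3	2	2	2	2	2	Ananas	Nymphaea	179
Zendovirus	Zendovirus-01	5	768	1	1	1	4	18	Fragaria	Rubus	41
Zendovirus	Zendovirus-02	37	11	1	1	1	2	4	Fragaria	Rosa	31
Zendovirus	Zendovirus-03	53	2	1	1	1	1	1	Pistacia	Pistacia	0
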