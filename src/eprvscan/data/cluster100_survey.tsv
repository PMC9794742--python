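cluster_n	n_seqs	genome	otu_cluster
1	951	Capsicum annuum	Solendovirus-01
2	77	Lotus japonicus	Florendovirus-01
3	53	Citrus maxima	Petuvirus-01
4	43	Hydrangea quercifolia	Florendovirus-01
5	27	Citrus medica	Petuvirus-01
6	26	Citrus medica	Petuvirus-01
7	24	Salvia splendens	Florendovirus-03
8	22	Ipomoea triloba	Petuvirus-05
9	21	Capsicum annuum	Yendovirus-02
10	20	Capsicum annuum	Florendovirus-03
11	20	Atalantia buxifolia	Petuvirus-01
12	19	Fortunella hindsii	Florendovirus-02
13	19	Atalantia buxifolia	Petuvirus-01
14	16	Helianthus annuus	Wendovirus-02
15	16	Ipomoea triloba	Dioscovirus-01
16	14	Fortunella hindsii	Florendovirus-02
17	13	Lactuca sativa	Florendovirus-03
18	12	Castanea dentata	Florendovirus-01
19	12	Atalantia buxifolia	Florendovirus-02
20	12	Nicotiana tabacum	Solendovirus-01
21	12	Lindenbergia philippensis	Tungrovirus-02
22	11	Lactuca sativa	Caulimovirus-01
23	11	Lotus japonicus	Florendovirus-01
24	11	Atalantia buxifolia	Florendovirus-02
25	11	Capsicum annuum	Florendovirus-03
26	11	Capsicum annuum	Solendovirus-01
27	10	Fragaria nilgerrensis	Florendovirus-01
28	10	Arachis hypogaea	Florendovirus-01
29	10	Nicotiana sylvestris	Solendovirus-01
30	10	Hordeum vulgare	Yendovirus-01
31	10	Rosa chinensis	Zendovirus-01
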