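species	phylum	n_loci	length_min	length_max	evidence	alternative_splicing
Nematostella vectensis	Cnidaria				/	No
Hydra magnipapillata	Cnidaria				/	No
Trichoplax adhaerens	Placozoa	5	120	178	1/5	No
Capitella teleta	Annelida	7	135	167	7/7	No
Helobdella robusta	Annelida	3	119	143	3/3	No
Lottia gigantea	Mollusca	7	132	163	7/7	No
Schmidtea mediterranea	Platyhelminthes	3	123	168	2/3	No
Schistosoma mansoni	Platyhelminthes	2	132	133	2/2	Yes
Schistosoma japonicum	Platyhelminthes	1	130	130	1/1	No
Echinococcus granulosus	Platyhelminthes	5	124	143	2/5	No
Echinococcus multilocularis	Platyhelminthes	5	124	143	4/4	No
Caenorhabditis elegans	Nematoda	9	135	165	9/9	Yes
Pristionchus pacificus	Nematoda	4	118	163	4/4	No
Heterorhabditis bacteriophora	Nematoda	3	133	164	3/3	No
Trichinella spiralis	Nematoda	3	133	143	3/3	No
Haemonchus contortus	Nematoda	0	133	164	4/4	No
Strongyloides ratti	Nematoda	4	132	165	4/4	No
Brugia malayi	Nematoda	3	130	180	3/3	No
Daphnia pulex	Arthropoda	2	130	131	2/2	No
Pediculus humanus corporis	Arthropoda	3	132	135	0/3	No
Bombyx mori	Arthropoda	5	95	142	4/5	No
Tribolium castaneum	Arthropoda	1	136	136	1/1	Yes
Nasonia vitripennis	Arthropoda	2	132	132	2/2	No
Acyrthosiphon pisum	Arthropoda	3	135	136	3/3	Yes
Apis mellifera	Arthropoda	2	132	133	2/2	Yes
Drosophila melanogaster	Arthropoda	1	130	130	1/1	Yes
Anopheles gambiae	Arthropoda	2	131	131	1/1	No
Aedes aegypti	Arthropoda	1	132	132	1/1	No
Culex pipiens quinquefasciatus	Arthropoda	1	132	132	1/1	No
Rhodnius prolixus	Arthropoda	1	134	134	1/1	No
Strongylocentrotus purpuratus	Echinodermata	2	130	130	2/2	No
Branchiostoma floridae	Chordata	15	135	151	7/14	No
Ciona savignyi	Chordata	3	127	133	3/3	No
Saccoglossus kowalevskii	Chordata	3	132	138	3/3	No
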