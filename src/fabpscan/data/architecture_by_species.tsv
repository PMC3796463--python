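species	phylum	6	5	4	3	2	1
Trichoplax adhaerens	Placozoa	1	1	3	0	0	0
Capitella teleta	Annelida	0	0	7	0	0	0
Helobdella robusta	Annelida	0	0	2	0	0	0
Lottia gigantea	Mollusca	0	1	7	0	0	0
Schmidtea mediterranea	Platyhelminthes	0	1	2	0	0	0
Schistosoma mansoni	Platyhelminthes	0	0	2	0	0	0
Schistosoma japonicum	Platyhelminthes	0	0	0	1	0	0
Echinococcus granulosus	Platyhelminthes	0	0	0	0	3	2
Echinococcus multilocularis	Platyhelminthes	0	0	0	0	3	2
Caenorhabditis elegans	Nematoda	0	0	1	4	4	0
Pristionchus pacificus	Nematoda	0	1	2	0	0	0
Heterorhabditis bacteriophora	Nematoda	0	2	1	0	0	0
Trichinella spiralis	Nematoda	0	0	3	0	0	0
Strongyloides ratti	Nematoda	0	0	0	0	1	3
Brugia malayi	Nematoda	0	0	2	1	0	0
Daphnia pulex	Arthropoda	0	0	1	1	0	0
Pediculus humanus corporis	Arthropoda	0	0	0	1	0	2
Bombyx mori	Arthropoda	0	0	4	1	0	0
Tribolium castaneum	Arthropoda	0	0	0	1	0	0
Nasonia vitripennis	Arthropoda	0	0	0	2	0	0
Acyrthosiphon pisum	Arthropoda	0	0	0	3	0	0
Apis mellifera	Arthropoda	0	0	1	1	0	0
Drosophila melanogaster	Arthropoda	0	0	0	1	0	0
Anopheles gambiae	Arthropoda	0	0	0	0	2	0
Aedes aegypti	Arthropoda	0	0	0	0	1	0
Culex pipiens quinquefasciatus	Arthropoda	0	0	0	0	1	0
Rhodnius prolixus	Arthropoda	0	0	0	0	0	1
Strongylocentrotus purpuratus	Echinodermata	0	0	0	0	1	1
Branchiostoma floridae	Chordata	0	0	12	3	0	0
Ciona savignyi	Chordata	0	0	2	1	0	0
Saccoglossus kowalevskii	Chordata	0	0	0	1	0	3
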