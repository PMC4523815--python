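organism	quantity_ug	genome_size_bp	rrna_copies	lineage
Clostridium phytofermentans ISDg	3.50	4847594	8	Bacteria; Firmicutes; Clostridia; Clostridiales; Clostridium
Natrinema pellirubrum str. J7-2	3.00	3697626	1	Archaea; Euryarchaeota; Halobacteria; Halobacteriales; Natrinema
Pantoea sp. AB-valens	1.50	4368708	1	Bacteria; Proteobacteria; Gammaproteobacteria; Enterobacteriales; Enterobacteriaceae; Pantoea
Rhodanobacter sp. 2APBS1	1.00	4225490	2	Bacteria; Proteobacteria; Gammaproteobacteria; Xanthomonadales; Xanthomonadaceae; Rhodanobacter
Natronobacterium gregoryi SP2	0.68	3788356	3	Archaea; Euryarchaeota; Halobacteria; Halobacteriales; Halobacteriaceae; Natronobacterium
Pseudoxanthomonas suwonensis 11-1	0.20	3419049	2	Bacteria; Proteobacteria; Gammaproteobacteria; Xanthomonadales; Xanthomonadaceae; Pseudoxanthomonas
Mycobacterium smegmatis JS623	0.06	6464916	2	Bacteria; Actinobacteria; Actinobacteria; Actinomycetales; Mycobacteriaceae; Mycobacterium
Halobacterium sp. str DL1	0.04	2846968	1	Archaea; Euryarchaeota; Halobacteria; Halobacteriales; Halobacteriaceae; Halobacterium
Paenibacillus lactis 154	0.02	6805951	1	Bacteria; Firmicutes; Bacilli; Bacillales; Paenibacillaceae; Paenibacillus
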