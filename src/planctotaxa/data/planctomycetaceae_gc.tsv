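# Genomic G+C content of Planctomycetaceae type strains (literature-compiled),
# with Phycisphaera mikurensis as outgroup.  reported_low/high: the range given
# in the species description (a point value has low == high; a value with a
# stated uncertainty is expanded to value +/- sd); genome_percent: G+C computed
# from the genome assembly.
taxon	reported_low	reported_high	genome_percent	outgroup
Blastopirellula marina	53.6	57.4	57.04	False
Gemmata obscuriglobus	63.4	65.4	67.18	False
Isosphaera pallida	62.2	62.2	62.49	False
Phycisphaera mikurensis	73.0	73.0	73.22	True
Pirellula staleyi	56.0	57.7	57.46	False
Planctomyces brasiliensis	55.1	57.7	56.45	False
Planctomyces limnophilus	52.65	53.83	53.68	False
Planctomyces maris	50.5	50.5	50.45	False
Rhodopirellula baltica	55.0	55.0	55.40	False
Schlesneria paludicola	56.3	56.3	55.66	False
Singulisphaera acidiphila	59.9	59.9	62.23	False
Zavarzinella formosa	62.5	62.5	59.10	False
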