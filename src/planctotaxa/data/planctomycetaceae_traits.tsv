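# Polyamines and polar lipids of Planctomycetaceae type strains as reported in
# the literature.  + present, - absent, NR not reported.  DPG diphosphatidyl-
# glycerol; Glyl glycolipid; PC phosphatidylcholine; DPE phosphatidyl-
# dimethylethanolamine; PG phosphatidylglycerol; MPE phosphatidyl-
# monomethylethanolamine.
taxon	Cadaverine	Putrescine	Spermidine	sym-Homospermidine	DPG	Glyl	PC	DPE	PG	MPE
Aquisphaera giovannonii	NR	NR	NR	NR	+	-	+	-	+	-
Blastopirellula cremea	NR	NR	NR	NR	-	-	-	-	+	-
Blastopirellula marina	-	-	-	+	+	-	-	-	+	-
Gemmata obscuriglobus	-	-	-	+	+	-	+	-	+	-
Isosphaera pallida	-	-	-	+	NR	NR	NR	NR	NR	NR
Pirellula staleyi	-	-	+	+	+	-	-	-	+	+
Planctomyces brasiliensis	-	-	+	+	+	+	-	-	+	-
Planctomyces limnophilus	-	+	+	-	+	+	-	-	+	-
Planctomyces maris	-	-	-	+	+	+	+	+	+	+
Rhodopirellula baltica	+	+	-	+	+	+	+	+	+	-
Singulisphaera acidiphila	NR	NR	NR	NR	-	-	+	-	+	-
Singulisphaera rosea	NR	NR	NR	NR	-	-	+	-	+	-
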