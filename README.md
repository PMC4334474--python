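# planctotaxa

Quantitative tools for revising prokaryotic taxonomy, built around the
question that arises whenever a named genus turns out to be paraphyletic in
molecular trees: *is the proposed regrouping supported by divergence,
significance tests, genome comparisons and phenotype — or only by habit?*
The motivating case is the family *Planctomycetaceae*, where the genus
*Planctomyces* is rendered paraphyletic by *Schlesneria*, but every component
is generic.

Intended users are microbial taxonomists and phylogeneticists who want the
individual analysis stages — divergence scoring, constrained-topology
significance testing, G+C emendation checks, genome distances, homolog-set
comparison, chemotaxonomic clustering — as composable, tested library
functions rather than a pipeline of external programs.

## What it computes

**MaSH divergence.** For a monophyletic group with most recent common
ancestor *m* on a tree with branch lengths in substitutions/site, the
maximum subtree height is

    MaSH(C) = max over tips x in C of  d(m, x)

with the stem branch above *m* excluded. On an ultrametric tree this equals
half the maximum within-group patristic distance, but it stays meaningful on
the non-ultrametric trees real data produce, and it is only defined for
monophyletic groups — which is the point: comparable divergence values for
candidate genera.

**Constrained topology tests.** The best tree under maximum likelihood
(GTR/HKY/JC ± discrete-Γ, pruning algorithm) or Fitch parsimony is compared
with the best tree satisfying a monophyly constraint. Per-site
log-likelihoods (or parsimony steps) feed the Kishino–Hasegawa test (paired
sites, two-sided, normal or RELL resampling) and the Shimodaira–Hasegawa
test (RELL with per-tree centering, which corrects for selecting the best
tree). Exhaustive search is supported to 8–10 tips ((2n−5)!! topologies),
NNI hill-climbing beyond.

**Genome metrics.** G+C content from assemblies (ambiguous bases excluded),
the emendation rule — flag a species description whose reported G+C differs
from the genome value by more than one percentage point — and the three
HSP-based genome distance fractions: f1 = HSP length / total length,
f2 = identities / HSP length, f3 = identities / total length, from an
in-package seed-and-extend HSP finder (exact k-mer seeds, ungapped x-drop
extension, both strands).

**Homolog-cluster sharing.** Markov clustering or thresholded connected
components on a gene similarity graph; Venn-region counts of cluster
presence across genomes and asymmetric shared-cluster percentages.

**Chemotaxonomy.** Arcsine–square-root transform of fatty-acid percentage
profiles, sum-deviation flagging (profiles off 100% by more than five
points), Ward clustering with a deterministic tie-break, and
present/absent/not-reported trait comparison for polyamines and polar
lipids.

**Synthetic data.** Seeded generators for each stage: Yule trees, alignments
evolved under the substitution models, genome pairs with programmed per-site
identity, cluster-presence patterns with programmed Venn regions, and
grouped compositional profiles. Same seed, same bytes.

## Worked example

```python
from planctotaxa import trees as tr, genome_metrics as gm

tree = tr.parse_newick(
    "((Pbra:0.036,Pmar:0.036):0.049,(Plim:0.037,Spal:0.037):0.048,Out:0.30);")
rooted = tr.midpoint_root(tree)
clades = [
    tr.CladeSpec("Pbra+Pmar", {"Pbra", "Pmar"}),
    tr.CladeSpec("Plim+Spal", {"Plim", "Spal"}),
    tr.CladeSpec("Planctomyces+Schlesneria", {"Pbra", "Pmar", "Plim", "Spal"}),
]
print(tr.mash_table({"16S": rooted}, clades))
print(gm.emendation_flag((63.4, 65.4), 67.18))
```

prints

```
                            16S
Pbra+Pmar                 0.036
Plim+Spal                 0.037
Planctomyces+Schlesneria  0.085
EmendationDecision(reported_low=63.4, reported_high=65.4, computed=67.18,
                   discrepancy=1.78..., flag=True, emended_value=67)
```

The two candidate two-species genera have nearly identical MaSH values
(0.036 vs 0.037 substitutions/site) while the four-species group is more
than twice as divergent — the kind of comparison that argues for splitting.
The emendation check flags a description reporting 64.4 ± 1.0% G+C against a
genome-computed 67.18%: the discrepancy of 1.78 points exceeds the
one-point rule, so the description should be emended to "about 67%".

A command-line interface mirrors the library
(`planctotaxa mash|score|mpscore|testmono|gc|ggdc|venn|chemo|simulate`);
every stochastic command takes `--seed`.

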