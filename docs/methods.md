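# Methods

This note records the models, conventions and numerical choices behind
`planctotaxa`, and what the synthetic-data tests do and do not establish.

## Trees and MaSH

Trees are rooted or unrooted (unrooted represented with a trifurcating root);
branch lengths are expected substitutions per site and are required — a
missing length is an error rather than an implicit zero, because every metric
here would silently be wrong otherwise. Newick parsing is delegated to
dendropy; serialization is an exact round-trip writer (`repr`-precision
lengths).

MaSH (maximum subtree height) of a clade is the largest MRCA-to-tip path
length inside the clade, excluding the stem branch above the MRCA. It
requires monophyly by construction; calling it on a non-monophyletic tip set
raises an error naming the intruding tips. Singleton clades get 0, for
generality. A clade equal to the whole tree has no stem branch; we measure
from the root. On ultrametric trees MaSH equals half the maximum within-clade
patristic distance (verified property); on non-ultrametric trees the two
deliberately differ.

Midpoint rooting places the root halfway along the longest tip-to-tip path.
Ties between equally long paths are broken by the lexicographically smallest
tip pair, so output is deterministic. An all-zero-length tree cannot be
midpoint-rooted; the root is kept with a warning. Monophyly and MaSH demand a
rooted tree (midpoint or outgroup rooting; the CLI exposes both).

## Substitution models and likelihood

JC69, HKY85 and GTR are parameterized by exchangeabilities and stationary
frequencies, with the rate matrix rescaled to mean rate 1 so branch lengths
stay in substitutions/site. Transition probabilities come from the
π-symmetrized eigendecomposition (numerically stable for reversible Q);
rows are renormalized after clipping tiny negative round-off. Among-site
rate variation uses the discrete-gamma approximation with equal-weight
categories whose rates are conditional means between quantile boundaries
(mean-of-quantiles; 4 categories by default, configurable). There is no
model selection: the defaults are a choice, exposed through configuration.

Per-site log-likelihoods use the pruning recursion with per-node rescaling
(scale factors accumulated in log space), so long trees do not underflow.
Ambiguity codes contribute partial likelihood 1 over their compatible
states; gaps and N are fully missing. Site patterns are compressed and the
per-alignment encodings cached, which is what makes exhaustive topology
scoring feasible.

Branch lengths on a fixed topology are optimized coordinate-wise by bounded
scalar search (bounds [1e-9, 10]), cycling until a full cycle gains less
than `tol` (default 1e-6 log-units, 20 cycles max). Only the sum of the two
root-adjacent branch lengths is identifiable for reversible models (pulley
principle); tests compare that sum, not the split. During tree search the
optimizer runs in a coarse regime (branches started at 0.1, per-branch
tolerance 1e-3, 4 cycles): topology ranking is robust to this, and the final
reported tree can be re-optimized tightly.

## Parsimony

Fitch (unordered) parsimony, per site and total. Gaps and N default to
missing data (full state set); a gap-as-fifth-state option exists. No step
matrices. The trifurcating root of an unrooted tree is resolved with a
zero-length edge before the bottom-up pass; the score is invariant to that
choice (verified against every rerooting).

## Topology enumeration, search and paired-site tests

Exhaustive enumeration produces all (2n−5)!! unrooted binary topologies by
sequential tip insertion; monophyly constraints are honored constructively
(each constrained group collapsed to a unit, backbone enumerated over units,
each group expanded into its (2k−3)!! rooted arrangements), never by
filtering, so constrained counts are exact. Nested or disjoint groups are
allowed; overlapping ones are rejected. Enumeration refuses more than 8 tips
by default (hard ceiling 10); NNI steepest-ascent hill-climbing is the
fallback, with constraint-violating moves skipped.

`exhaustive_comparison` scores every topology exactly once and takes maxima
over the full set and over each constraint-satisfying subset. The
restriction property — a constrained optimum never beats the unconstrained
one, with equality whenever the unconstrained optimum satisfies the
constraint — therefore holds exactly, not merely up to optimizer noise.

KH test: per-site differences δ, H0 E[δ]=0, two-sided. The normal method is
a t statistic on δ; the RELL method resamples sites with replacement from
centered differences (multinomial site counts), p = (exceedances+1)/(B+1).
SH test: RELL totals for every candidate, centered per tree, p for tree t is
the (+1-corrected) fraction of resamples whose centered best-minus-t
difference reaches the observed difference. The best tree's p is 1 by
construction and bounds the others. Defaults: B=1000, seed mandatory in the
CLI. Bootstrap support resamples alignment columns, reruns the search and
counts canonical bipartitions (side not containing the smallest label).

## Genome metrics

G+C excludes ambiguity codes from numerator and denominator (the alternative
— counting S toward G+C — changes values by <0.01% on real assemblies but is
not what "percent of unambiguous bases" means). The emendation rule flags a
description when the genome value lies more than 1.0 percentage point
outside the reported value or range, and reports the nearest-integer emended
value for "about NN%" wording. Multi-record (draft) assemblies concatenate
logically for length and G+C.

HSPs: exact k-mer seeds (default k=11) on both strands, ungapped extension
at +1/−1 with an x-drop stop (default 20), trimmed back to the
maximum-score segment; seeds inside an already-extended span on the same
diagonal are skipped, merging overlaps; records of draft assemblies are
compared independently and extensions never cross record boundaries.
Coordinates are 0-based half-open; minus-strand HSPs carry plus-strand
coordinates and a strand flag. Scores below `min_score` (default 30) are
discarded.

The distance fractions use "total length" = mean of the two genome lengths,
so identical genomes score 1.0 on all three formulas (configurable to the
sum). f3 = f1·f2 by construction. The regression that would convert these
fractions into DNA–DNA-hybridization percentages is out of scope; raw
fractions are reported.

## Homolog clusters

The similarity graph is ingested as an edge list (`genome|gene` ids); graph
construction from alignments is out of scope, keeping the package
download-free. Clustering is either thresholded connected components or an
in-package Markov clustering (column-normalized adjacency with self-loops,
expansion by squaring, element-wise inflation, pruning at 1e-12, iteration
to 1e-6; hard clusters from attractor rows, overlaps merged). MCL here is
deterministic — no randomness enters.

Venn regions count *clusters* (not genes) present in exactly each subset of
the listed genomes; singleton genes are singleton clusters and count in
their genome's totals. Shared fraction of genome a with b is
100 × (clusters containing both) / (clusters containing a) — asymmetric by
definition, which is why a can share 63% with b while b shares less with a.

## Chemotaxonomy

Percentages are transformed as arcsin(sqrt(x/100)) (we take the transform to
act on proportions of 1, i.e. percent/100). Profiles whose non-missing
entries sum more than five points away from 100 are flagged; missing values
count as zero there, deliberately, since an incomplete profile is exactly
what the flag should expose. Before clustering, missing values are imputed
as zero ("trace below detection"; row-mean imputation available).

Ward clustering uses the Lance–Williams recurrence on squared Euclidean
distances with square-root heights (the ward.D2-on-observations convention,
matching `scipy.cluster.hierarchy.linkage(method="ward")`, to which it is
cross-checked); two Ward conventions circulate, so this one is stated
explicitly. Ties are broken by the lexicographically smallest cluster-index
pair. Columns are not standardized before clustering. The tested surface is
the flag vector, the transformed matrix, the merge sequence and the leaf
order; the heat map is a thin optional matplotlib layer.

Trait comparison counts +/− disagreements over traits reported for both
taxa; NR cells are excluded from both numerator and denominator.

## Synthetic data

Generators are pure functions of (parameters, seed); substreams are derived
by hashing a stream name into the seed sequence, so adding draws to one
generator never shifts another's output. Yule trees use the fixed-n
construction (n−1 exponential waiting times, uniformly chosen splitter), so
tip counts are exact and trees are ultrametric unless branchwise lognormal
rate noise is requested. Alignment simulation draws root states from the
stationary distribution and propagates with the model's transition matrices
(per-site gamma rates drawn first). Genome pairs are uniform-random
sequences with i.i.d. substitutions to a different base — no indels or
rearrangements, so HSP coverage approaches 100% and formula 2 estimates
1 − substitution rate directly. Cluster-presence simulation builds each
Venn region explicitly (round-trip oracle). Profile simulation places group
centers on the percent simplex, pulls each toward a signature acid by the
separation parameter, adds truncated Gaussian noise and renormalizes to 100.

What the generators do *not* emulate: alignment error and gaps,
compositional heterogeneity across lineages, genome rearrangement and
repeats, gene-family birth–death, inter-laboratory measurement bias in
fatty-acid profiles. Passing tests therefore demonstrate algorithmic
correctness and calibration under the stated models, not robustness to
those real-data complications.

## Problem sizes and calibration conditions

Chosen once as the package's standard desk-scale study conditions:

- MaSH/patristic equivalence: 100 ultrametric Yule trees, 20 tips, every
  internal clade.
- Likelihood oracle: all 3 quartet topologies, uniform(0.02, 0.5) branch
  lengths, 6 sites, JC and GTR+Γ4, tolerance 1e-10.
- Parsimony oracle: 50 random 6-tip instances, 6 sites, exhaustive minimum
  over 4^5 internal assignments.
- KH calibration: 500 replicates of 1000 i.i.d. N(0,1) site differences,
  RELL B=199, α=0.05; expected rejection within the binomial 99% band
  [0.032, 0.071]. SH: 500 replicates of 3 exchangeable candidates
  (shared N(0,1) site signal plus N(0, 0.5) per-tree noise), B=1000; the
  rejection rate of candidate trees sits at or just below α — SH's
  conservativeness guarantee is asymptotic, and at these sizes the measured
  rate fluctuates around 0.05 by Monte-Carlo noise (≈±0.006).
- Constrained-search property: 20 datasets, each a uniformly drawn 6-tip
  topology with i.i.d. uniform(0.05, 0.3) branch lengths and a 400-site JC
  alignment — a regime where every branch carries recoverable signal, so
  the true-clade constraint should (and does) coincide with the
  unconstrained optimum. Yule trees were deliberately not used here: their
  near-zero internal branches make clade recovery a coin flip at desk
  scale, which would test signal strength rather than the search.
- HSP formula recovery: 10 pairs of 50 kb at 5% divergence, k=11, xdrop=20.
- Ward oracle: 5-row matrices against exhaustive variance-increase search.

## Known limitations

Exhaustive search is exponential; NNI is a local heuristic without restarts
by default. The likelihood engine is for small (≤ ~15 tip) problems — there
is no analytic-derivative optimizer or SIMD kernel. The HSP finder is a
minimal seed-and-extend aligner: no gapped extension, no masking of
low-complexity sequence, quadratic behavior possible on highly repetitive
genomes. MCL inflation defaults (2.0) suit the planted-partition regime
tested; real similarity graphs may need tuning. The G+C literature table
ships with the package for the emendation analysis; recomputing its genome
column requires the public assemblies and is intentionally outside the test
suite.
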