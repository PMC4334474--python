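"""Seeded generators for every input the analysis stages consume.

Each generator emulates the statistical structure one stage assumes — trees
with known heights for divergence scoring, alignments evolved under a known
model for likelihood and test calibration, genome pairs with a programmed
per-site identity for distance-formula recovery, cluster-presence patterns
for the Venn analysis, and grouped compositional profiles for the
chemotaxonomic clustering — so every stage can be tested end-to-end without
downloading data.

All generators are pure functions of their arguments: the same seed yields
byte-identical output.  Independent substreams are derived per generator by
hashing the stream name into the seed sequence, so adding a draw to one
generator never shifts another's stream.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from .chemotax import ProfileMatrix
from .genome_metrics import GenomeSequence
from .homolog_clusters import ClusterSet, SimilarityGraph
from .seqmodels import Alignment, SubstitutionModel, transition_probabilities
from .trees import Node, PhyloTree

__all__ = [
    "substream",
    "simulate_tree",
    "simulate_alignment",
    "simulate_genome_pair",
    "simulate_cluster_presence",
    "simulate_profiles",
]

DNA = np.array(list("ACGT"))


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream for (seed, stream name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2 ** 31), zlib.crc32(name.encode())])
    )


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0,
                  rate_sigma: float = 0.0) -> PhyloTree:
    """Yule (pure-birth) tree with exactly ``n_tips`` tips.

    Construction draws the n-1 inter-speciation waiting times directly
    (exponential with rate k*birth_rate while k lineages exist) and splits a
    uniformly chosen lineage at each event, so the tip count is exact.  With
    ``rate_sigma`` 0 the tree is ultrametric; otherwise each branch length is
    multiplied by an independent lognormal(0, rate_sigma) factor, giving a
    relaxed-clock (non-ultrametric) tree.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    if rate_sigma < 0:
        raise ValueError("rate_sigma must be non-negative")
    rng = substream(seed, f"tree-{n_tips}-{birth_rate}-{rate_sigma}")
    width = len(str(n_tips))
    root = Node(None, None)
    birth = {root: 0.0}
    lineages = [root]
    t = 0.0
    while len(lineages) < n_tips:
        t += rng.exponential(1.0 / (len(lineages) * birth_rate))
        parent = lineages.pop(rng.integers(len(lineages)))
        parent.length = (t - birth[parent]) if parent.parent is not None else None
        for _ in range(2):
            child = Node(None, None)
            parent.add_child(child)
            birth[child] = t
            lineages.append(child)
    present = t + rng.exponential(1.0 / (n_tips * birth_rate))
    for i, leaf in enumerate(sorted(lineages, key=lambda n: birth[n])):
        leaf.label = f"t{i + 1:0{width}d}"
        leaf.length = present - birth[leaf]
    # the root split happens at the first event: shift so the root is at 0
    tree = PhyloTree(root)
    if rate_sigma > 0:
        for node in tree.postorder():
            if node is not tree.root:
                node.length *= float(rng.lognormal(0.0, rate_sigma))
    return tree


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel,
                       n_sites: int, seed: int = 0) -> Alignment:
    """Evolve an alignment along a tree under a substitution model.

    Root states are drawn from the model's stationary frequencies; each
    branch applies the model's transition probabilities (per-site gamma rate
    factors drawn first if the model has among-site rate variation).
    """
    if n_sites < 1:
        raise ValueError("need at least one site")
    tree.require_branch_lengths()
    rng = substream(seed, f"alignment-{n_sites}")
    n_states = model.n_states
    pi = np.asarray(model.base_frequencies, float)
    rates = model.category_rates()
    site_rate = rates[rng.integers(len(rates), size=n_sites)] \
        if len(rates) > 1 else np.ones(n_sites)
    unique_rates = np.unique(site_rate)

    states = {tree.root: rng.choice(n_states, size=n_sites, p=pi)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_states = states[node.parent]
        child = np.empty(n_sites, dtype=np.int64)
        for r in unique_rates:
            sel = site_rate == r
            P = transition_probabilities(model, node.length * r)
            cum = np.cumsum(P, axis=1)
            u = rng.random(int(sel.sum()))
            ps = parent_states[sel]
            child[sel] = (u[:, None] > cum[ps]).sum(axis=1)
        states[node] = child
    symbols = np.array(list(model.states))
    seqs = {
        n.label: "".join(symbols[states[n]])
        for n in tree.postorder() if n.is_tip
    }
    return Alignment(seqs, alphabet="dna" if n_states == 4 else "ry")


def simulate_genome_pair(length: int, sub_prob: float,
                         seed: int = 0) -> tuple:
    """Genome pair with programmed per-site divergence and no indels.

    Genome A is uniform random over ACGT; B substitutes each site
    independently with probability ``sub_prob`` to a uniformly chosen
    *different* base, so the expected mismatch fraction equals ``sub_prob``.
    """
    if not 0 <= sub_prob < 0.75:
        raise ValueError("sub_prob must be in [0, 0.75)")
    rng = substream(seed, f"genomes-{length}-{sub_prob}")
    a = rng.integers(4, size=length)
    hit = rng.random(length) < sub_prob
    shift = rng.integers(1, 4, size=length)
    b = np.where(hit, (a + shift) % 4, a)
    genome_a = GenomeSequence([("A", "".join(DNA[a]))])
    genome_b = GenomeSequence([("B", "".join(DNA[b]))])
    return genome_a, genome_b


def simulate_cluster_presence(n_genomes: int, region_counts: dict,
                              genes_per_cluster: int = 1,
                              seed: int = 0) -> tuple:
    """Cluster sets with programmed Venn-region counts, plus their graph.

    ``region_counts`` maps subsets of genome names (any iterable of strings)
    to the number of clusters present in exactly that subset.  Genomes are
    named g1..gN when referenced by the produced graph.  Returns
    ``(SimilarityGraph, ClusterSet)``; running the Venn-region count on the
    cluster set reproduces ``region_counts`` exactly (the round-trip oracle).
    """
    if genes_per_cluster < 1:
        raise ValueError("genes_per_cluster must be at least 1")
    genomes = [f"g{i + 1}" for i in range(n_genomes)]
    for sub, count in region_counts.items():
        if count < 0:
            raise ValueError("negative region count")
        if not set(sub) <= set(genomes):
            raise ValueError(f"unknown genomes in region {sorted(sub)}")
    graph = SimilarityGraph()
    clusters = []
    serial = 0
    for sub in sorted(region_counts, key=lambda s: sorted(s)):
        for _ in range(region_counts[sub]):
            serial += 1
            members = [
                f"{g}|c{serial}_{i}"
                for g in sorted(sub)
                for i in range(genes_per_cluster)
            ]
            clusters.append(members)
            if len(members) == 1:
                graph.add_node(members[0])
            for x, y in zip(members, members[1:]):
                graph.add_edge(x, y, 1.0)
    return graph, ClusterSet(clusters)


def simulate_profiles(n_groups: int, rows_per_group: int, n_acids: int,
                      center_separation: float = 30.0, noise_sd: float = 1.0,
                      seed: int = 0) -> tuple:
    """Grouped compositional fatty-acid profiles with Gaussian noise.

    Group centers lie on the percent simplex; each group's center is pulled
    toward its own signature acid by ``center_separation`` (in percentage
    points) so groups are separable.  Rows add truncated Gaussian noise
    (sd ``noise_sd``) and are renormalized to sum exactly 100.  Returns
    ``(ProfileMatrix, group_labels)``.
    """
    if min(n_groups, rows_per_group, n_acids) < 1:
        raise ValueError("all size parameters must be positive")
    if n_groups > n_acids:
        raise ValueError("need at least as many acids as groups")
    if noise_sd < 0 or center_separation < 0:
        raise ValueError("noise_sd and center_separation must be >= 0")
    rng = substream(seed, f"profiles-{n_groups}-{rows_per_group}-{n_acids}")
    centers = rng.dirichlet(np.ones(n_acids), size=n_groups) * 100.0
    for g in range(n_groups):
        centers[g, g] += center_separation
        centers[g] *= 100.0 / centers[g].sum()
    rows, index, groups = [], [], []
    for g in range(n_groups):
        for r in range(rows_per_group):
            row = centers[g] + rng.normal(0.0, noise_sd, size=n_acids) \
                if noise_sd > 0 else centers[g].copy()
            row = np.clip(row, 0.0, None)
            row *= 100.0 / row.sum()
            rows.append(row)
            index.append((f"group{g + 1}", f"rep{r + 1}"))
            groups.append(g)
    df = pd.DataFrame(
        rows,
        index=pd.MultiIndex.from_tuples(index, names=["taxon", "source"]),
        columns=[f"FA{i + 1}" for i in range(n_acids)],
    )
    return ProfileMatrix(df), groups
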