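"""Homolog families from similarity graphs, and their sharing across genomes.

Genes from several genomes are clustered into families of homologs from a
precomputed similarity graph (edge weights from any aligner's tabular
output).  Two clusterings are available: connected components above a weight
threshold, and Markov clustering (MCL), the flow-simulation algorithm that
TribeMCL applies to protein similarity graphs.  The resulting cluster set is
then compared set-theoretically across genomes: counts of clusters present in
exactly each subset of genomes (the regions of a Venn diagram) and the
fraction of a genome's clusters shared with another genome.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "SimilarityGraph",
    "ClusterSet",
    "read_edge_list",
    "cluster_homologs",
    "venn_regions",
    "shared_fraction",
]


class SimilarityGraph:
    """Gene similarity graph; gene ids are ``genome|gene`` strings."""

    def __init__(self, edges=(), nodes=()):
        self.graph = nx.Graph()
        for node in nodes:
            self.add_node(node)
        for a, b, w in edges:
            self.add_edge(a, b, w)

    @staticmethod
    def genome_of(gene_id: str) -> str:
        if "|" not in gene_id:
            raise ValueError(
                f"gene id {gene_id!r} is not in genome|gene form")
        return gene_id.split("|", 1)[0]

    def add_node(self, gene_id: str):
        self.graph.add_node(gene_id, genome=self.genome_of(gene_id))

    def add_edge(self, a: str, b: str, weight: float):
        if a == b:
            raise ValueError(f"self-edge on {a!r}")
        if not np.isfinite(weight) or weight < 0:
            raise ValueError(f"invalid edge weight {weight!r}")
        self.add_node(a)
        self.add_node(b)
        self.graph.add_edge(a, b, weight=float(weight))

    @property
    def genomes(self) -> set:
        return {d["genome"] for _, d in self.graph.nodes(data=True)}

    def __len__(self):
        return self.graph.number_of_nodes()


def read_edge_list(path) -> SimilarityGraph:
    """TSV edge list: geneA<TAB>geneB<TAB>weight."""
    g = SimilarityGraph()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b, w = line.split("\t")
            g.add_edge(a, b, float(w))
    return g


@dataclass(frozen=True)
class ClusterSet:
    """A partition of genes into homolog clusters."""

    clusters: tuple  # of frozensets of gene ids

    def __init__(self, clusters):
        clusters = tuple(frozenset(c) for c in clusters)
        seen: set = set()
        for c in clusters:
            if not c:
                raise ValueError("empty cluster")
            if seen & c:
                raise ValueError("clusters overlap; not a partition")
            seen |= c
        object.__setattr__(self, "clusters", clusters)

    @property
    def genome_presence(self) -> tuple:
        """Per cluster, the set of genomes with at least one member."""
        return tuple(
            frozenset(SimilarityGraph.genome_of(g) for g in c)
            for c in self.clusters
        )

    @property
    def genomes(self) -> set:
        return set().union(*self.genome_presence) if self.clusters else set()

    def __len__(self):
        return len(self.clusters)


def cluster_homologs(graph: SimilarityGraph, method: str = "components",
                     threshold: float = 0.0, inflation: float = 2.0,
                     max_iter: int = 100, tol: float = 1e-6) -> ClusterSet:
    """Cluster genes into homolog families.

    ``components``: connected components after removing edges with weight
    below ``threshold``; isolated genes become singleton clusters.
    ``mcl``: Markov clustering — column-normalize the weighted adjacency
    (with self-loops), alternate expansion (matrix squaring) and inflation
    (element-wise power ``inflation`` then renormalization) until the matrix
    change falls below ``tol``, and read hard clusters off the attractor
    rows.  MCL is deterministic: no randomness is involved.
    """
    g = graph.graph
    if g.number_of_nodes() == 0:
        return ClusterSet(())
    if method == "components":
        if threshold < 0:
            raise ValueError("threshold must be non-negative")
        kept = nx.Graph()
        kept.add_nodes_from(g.nodes)
        kept.add_edges_from(
            (a, b) for a, b, w in g.edges(data="weight") if w >= threshold
        )
        return ClusterSet(tuple(nx.connected_components(kept)))
    if method == "mcl":
        if inflation <= 1:
            raise ValueError("inflation must exceed 1")
        nodes = sorted(g.nodes)
        M = nx.to_numpy_array(g, nodelist=nodes, weight="weight")
        np.fill_diagonal(M, 1.0)  # self-loops stabilize the iteration
        M /= M.sum(axis=0, keepdims=True)
        for _ in range(max_iter):
            previous = M
            M = M @ M
            M = np.power(M, inflation)
            M[M < 1e-12] = 0.0
            M /= M.sum(axis=0, keepdims=True)
            if np.abs(M - previous).max() < tol:
                break
        else:
            warnings.warn("MCL did not converge; using current state")
        attractors = np.nonzero(np.diag(M) > 1e-6)[0]
        membership = nx.Graph()
        membership.add_nodes_from(range(len(nodes)))
        for i in attractors:
            for j in np.nonzero(M[i] > 1e-6)[0]:
                membership.add_edge(i, j)
        return ClusterSet(tuple(
            frozenset(nodes[i] for i in comp)
            for comp in nx.connected_components(membership)
        ))
    raise ValueError(f"unknown method {method!r}")


def venn_regions(cs: ClusterSet, genomes) -> dict:
    """Cluster counts for every non-empty subset of ``genomes``.

    A cluster is counted in the region matching exactly the subset of the
    listed genomes it is present in; clusters also present in unlisted
    genomes still count by their restriction to the listed ones.  Counts over
    all regions sum to the number of clusters touching at least one listed
    genome.
    """
    genomes = list(genomes)
    if not 2 <= len(genomes) <= 6:
        raise ValueError("venn_regions supports 2 to 6 genomes")
    present = cs.genomes
    missing = [g for g in genomes if g not in present]
    if missing:
        raise ValueError(f"genomes absent from the cluster set: {missing}")
    counts = {
        frozenset(sub): 0
        for r in range(1, len(genomes) + 1)
        for sub in itertools.combinations(genomes, r)
    }
    for presence in cs.genome_presence:
        region = frozenset(presence) & frozenset(genomes)
        if region:
            counts[region] += 1
    return counts


def shared_fraction(cs: ClusterSet, a: str, b: str) -> float:
    """Percent of genome ``a``'s clusters that also contain genome ``b``.

    Asymmetric: the denominator is the number of clusters with at least one
    gene of ``a`` (singleton clusters included).
    """
    n_a = n_both = 0
    for presence in cs.genome_presence:
        if a in presence:
            n_a += 1
            if b in presence:
                n_both += 1
    if n_a == 0:
        raise ValueError(f"genome {a!r} has no clusters")
    if b not in cs.genomes:
        raise ValueError(f"genome {b!r} has no clusters")
    return 100.0 * n_both / n_a


def write_clusters(cs: ClusterSet, path) -> None:
    """MCL-style output: one cluster per line, tab-separated gene ids."""
    with open(path, "w") as fh:
        for cluster in cs.clusters:
            fh.write("\t".join(sorted(cluster)) + "\n")
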