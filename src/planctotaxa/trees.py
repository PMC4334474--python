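"""Phylogenetic trees: Newick I/O, tree metrics, and the MaSH divergence statistic.

The central quantity here is the *maximum subtree height* (MaSH) of a clade:
the largest path length, in expected substitutions per site, from the clade's
most recent common ancestor to any tip of the clade, with the branch leading
into that ancestor (the stem) excluded.  On an ultrametric (clock-like) tree
MaSH equals half the maximum within-clade patristic distance; on the
non-ultrametric trees that molecular data usually produce it remains well
defined, and because it is computed from a subtree it can only be evaluated
for monophyletic groups.  Comparing MaSH values across named groups gives a
direct, tree-based measure of how divergent each group is, which is the basis
for deciding whether groups of species are too divergent to share a genus.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import dendropy
import pandas as pd

__all__ = [
    "TreeError",
    "NewickParseError",
    "Node",
    "PhyloTree",
    "CladeSpec",
    "MashValue",
    "parse_newick",
    "read_newick",
    "write_newick",
    "patristic_distance",
    "patristic_matrix",
    "mrca",
    "is_monophyletic",
    "midpoint_root",
    "outgroup_root",
    "mash",
    "mash_table",
    "read_clade_specs",
]


class TreeError(ValueError):
    """Invalid tree, label or clade input."""


class NewickParseError(TreeError):
    """Malformed Newick text."""


class Node:
    """A node of a :class:`PhyloTree`.

    ``length`` is the length of the branch connecting the node to its parent
    (``None`` for the root, or when the input tree carried no length).
    """

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.parent = None
        self.children = []

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover
        kind = "tip" if self.is_tip else "node"
        return f"<{kind} {self.label!r} len={self.length}>"


class PhyloTree:
    """Rooted or unrooted phylogenetic tree with branch lengths.

    Unrooted trees are represented, by the usual convention, with a
    trifurcating root node.  ``rooted`` reflects that convention: a tree is
    considered rooted iff its root is bifurcating (or the tree has fewer than
    three tips).
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation ------------------------------------------------

    def _validate(self):
        seen = set()
        for node in self.postorder():
            if node.is_tip:
                if node.label is None or node.label == "":
                    raise TreeError("tip without a label")
                if node.label in seen:
                    raise TreeError(f"duplicate tip label: {node.label!r}")
                seen.add(node.label)
            if node.length is not None and node.length < 0:
                raise TreeError(
                    f"negative branch length {node.length} at {node.label!r}"
                )

    @property
    def rooted(self) -> bool:
        return len(self.root.children) <= 2

    # -- traversal ---------------------------------------------------------------

    def postorder(self):
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> dict:
        """Map tip label -> Node, in postorder."""
        return {n.label: n for n in self.postorder() if n.is_tip}

    def tip_labels(self) -> list:
        return sorted(self.tips())

    def node_for(self, label: str) -> Node:
        try:
            return self.tips()[label]
        except KeyError:
            raise TreeError(f"unknown tip label: {label!r}") from None

    def require_branch_lengths(self):
        for node in self.postorder():
            if node is not self.root and node.length is None:
                raise TreeError(
                    f"branch length missing on edge above {node.label!r}; "
                    "metrics require lengths on every branch"
                )

    def copy(self) -> "PhyloTree":
        def clone(n):
            c = Node(n.label, n.length)
            for ch in n.children:
                c.add_child(clone(ch))
            return c

        return PhyloTree(clone(self.root))

    def total_length(self) -> float:
        return sum(
            n.length or 0.0 for n in self.postorder() if n is not self.root
        )

    def __repr__(self):  # pragma: no cover
        return f"<PhyloTree {len(self.tips())} tips rooted={self.rooted}>"


@dataclass(frozen=True)
class CladeSpec:
    """A named group of tips whose monophyly and divergence are of interest."""

    name: str
    tips: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "tips", frozenset(self.tips))
        if not self.tips:
            raise TreeError(f"clade {self.name!r} has no tips")


@dataclass(frozen=True)
class MashValue:
    """Maximum subtree height of a clade on one tree, stem branch excluded."""

    clade_name: str
    value: float
    tree_id: str = ""


# -- Newick I/O -----------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a single Newick statement into a :class:`PhyloTree`.

    Labels and branch lengths are preserved verbatim; internal-node labels
    (often bootstrap supports) are carried but not interpreted.
    """
    if not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from None

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    root.length = None
    return PhyloTree(root)


def read_newick(path) -> list:
    """Read one tree per non-empty line from a Newick file."""
    with open(path) as fh:
        return [parse_newick(line) for line in fh if line.strip()]


def _format_length(x: float) -> str:
    return repr(float(x)) if x is not None else None


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick; round-trips exactly through parse_newick."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            s = node.label
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.label:
                s += node.label
        if node.length is not None:
            s += ":" + _format_length(node.length)
        return s

    return fmt(tree.root) + ";"


# -- metrics --------------------------------------------------------------------


def _depths_from(node: Node) -> dict:
    """Path length from ``node`` to every descendant node."""
    out = {node: 0.0}
    stack = [node]
    while stack:
        n = stack.pop()
        for c in n.children:
            if c.length is None:
                raise TreeError(f"branch length missing above {c.label!r}")
            out[c] = out[n] + c.length
            stack.append(c)
    return out


def _ancestors(node: Node) -> list:
    out = []
    while node is not None:
        out.append(node)
        node = node.parent
    return out


def patristic_distance(tree: PhyloTree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between tips ``a`` and ``b``."""
    na, nb = tree.node_for(a), tree.node_for(b)
    if na is nb:
        return 0.0
    tree.require_branch_lengths()
    anc_a = _ancestors(na)
    set_a = set(anc_a)
    dist_b = 0.0
    node = nb
    while node not in set_a:
        dist_b += node.length
        node = node.parent
    dist_a = 0.0
    for n in anc_a:
        if n is node:
            break
        dist_a += n.length
    return dist_a + dist_b


def patristic_matrix(tree: PhyloTree) -> pd.DataFrame:
    """All-pairs patristic distances between tips (labels sorted)."""
    labels = tree.tip_labels()
    df = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = patristic_distance(tree, a, b)
            df.loc[a, b] = df.loc[b, a] = d
    return df


def mrca(tree: PhyloTree, labels) -> Node:
    """Most recent common ancestor of the given tips (rooted trees)."""
    labels = set(labels)
    tips = tree.tips()
    missing = labels - set(tips)
    if missing:
        raise TreeError(f"unknown tip labels: {sorted(missing)}")
    nodes = [tips[x] for x in labels]
    common = set(_ancestors(nodes[0]))
    for n in nodes[1:]:
        common &= set(_ancestors(n))
    # the MRCA is the deepest common ancestor: the longest chain to the root
    return max(common, key=lambda n: len(_ancestors(n)))


def _tipset_below(node: Node) -> set:
    out = set()
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_tip:
            out.add(n.label)
        stack.extend(n.children)
    return out


def is_monophyletic(tree: PhyloTree, clade: CladeSpec):
    """Whether ``clade.tips`` are all and only the descendants of their MRCA.

    Returns ``(flag, mrca_node)``.  Requires a rooted tree: monophyly is not
    defined on an unrooted tree without first choosing a root.
    """
    if not tree.rooted:
        raise TreeError(
            "monophyly requires a rooted tree; root it first "
            "(midpoint_root or outgroup_root)"
        )
    anc = mrca(tree, clade.tips)
    return _tipset_below(anc) == set(clade.tips), anc


# -- rooting --------------------------------------------------------------------


def _adjacency(tree: PhyloTree) -> dict:
    adj = {}
    for node in tree.postorder():
        adj.setdefault(node, [])
        for c in node.children:
            adj[node].append((c, c.length))
            adj.setdefault(c, []).append((node, c.length))
    return adj


def _suppress_unifurcations(root: Node) -> Node:
    """Remove internal nodes of out-degree 1 (merging branch lengths)."""
    stack = [root]
    while stack:
        node = stack.pop()
        for i, child in enumerate(list(node.children)):
            while len(child.children) == 1 and not child.is_tip:
                grand = child.children[0]
                grand.length = (grand.length or 0.0) + (child.length or 0.0)
                grand.parent = node
                node.children[i] = grand
                child = grand
            stack.append(child)
    while len(root.children) == 1 and not root.children[0].is_tip:
        root = root.children[0]
        root.parent = None
        root.length = None
    return root


def _rebuild_from(adj: dict, root_obj, extra=None) -> PhyloTree:
    """Orient an undirected adjacency away from ``root_obj`` into a new tree."""
    new = {}

    def build(node, parent, length):
        fresh = Node(node.label, length)
        new[node] = fresh
        for nbr, ln in adj[node]:
            if nbr is not parent:
                fresh.add_child(build(nbr, node, ln))
        return fresh

    root = build(root_obj, None, None)
    root = _suppress_unifurcations(root)
    root.length = None
    return PhyloTree(root)


def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root the tree at the midpoint of its longest tip-to-tip path.

    The two deepest root-to-tip paths of the result are equal (to numerical
    precision).  Ties between equally long tip pairs are broken by the
    lexicographically smallest sorted pair, so the result is deterministic.
    Patristic distances are unchanged by rerooting.
    """
    tree = tree.copy()
    tree.require_branch_lengths()
    labels = tree.tip_labels()
    if len(labels) < 2:
        return tree
    dm = patristic_matrix(tree)
    best = None
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            d = dm.loc[a, b]
            if best is None or d > best[0] + 1e-15:
                best = (d, a, b)
    diameter, a, b = best
    if diameter == 0.0:
        warnings.warn("all branch lengths are zero; keeping existing root")
        return tree

    # path from a to b through the current (arbitrary) root
    na, nb = tree.node_for(a), tree.node_for(b)
    anc_a = _ancestors(na)
    set_a = set(anc_a)
    up_b = [nb]
    while up_b[-1] not in set_a:
        up_b.append(up_b[-1].parent)
    top = up_b[-1]
    path = anc_a[: anc_a.index(top) + 1] + list(reversed(up_b[:-1]))

    half = diameter / 2.0
    adj = _adjacency(tree)
    run = 0.0
    for u, v in zip(path, path[1:]):
        step = v.length if v.parent is u else u.length
        if run + step >= half - 1e-15:
            offset = half - run  # distance from u toward v
            if offset <= 1e-15:
                return _rebuild_from(adj, u)
            if abs(offset - step) <= 1e-15:
                return _rebuild_from(adj, v)
            mid = Node(None, None)
            adj[u] = [(n, l) for n, l in adj[u] if n is not v]
            adj[v] = [(n, l) for n, l in adj[v] if n is not u]
            adj[mid] = [(u, offset), (v, step - offset)]
            adj[u].append((mid, offset))
            adj[v].append((mid, step - offset))
            return _rebuild_from(adj, mid)
        run += step
    raise AssertionError("midpoint not found on diameter path")  # pragma: no cover


def outgroup_root(tree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root on the branch leading to ``outgroup``, splitting it in half."""
    tree = tree.copy()
    node = tree.node_for(outgroup)
    if node is tree.root:
        raise TreeError("outgroup is already the root")
    tree.require_branch_lengths()
    adj = _adjacency(tree)
    parent = node.parent
    mid = Node(None, None)
    half = node.length / 2.0
    adj[parent] = [(n, l) for n, l in adj[parent] if n is not node]
    adj[node] = [(n, l) for n, l in adj[node] if n is not parent]
    adj[mid] = [(node, half), (parent, node.length - half)]
    adj[node].append((mid, half))
    adj[parent].append((mid, node.length - half))
    return _rebuild_from(adj, mid)


# -- MaSH -----------------------------------------------------------------------


def mash(tree: PhyloTree, clade: CladeSpec, tree_id: str = "") -> MashValue:
    """Maximum subtree height of a monophyletic clade, stem branch excluded.

    The value is the largest path length from the clade's MRCA to any of its
    tips.  The stem branch (leading into the MRCA) does not contribute.  A
    singleton clade has height 0 by convention.
    """
    mono, anc = is_monophyletic(tree, clade)
    if not mono:
        intruders = sorted(_tipset_below(anc) - set(clade.tips))
        raise TreeError(
            f"clade {clade.name!r} is not monophyletic; "
            f"intruding tips: {intruders}"
        )
    depths = _depths_from(anc) if len(clade.tips) > 1 else {anc: 0.0}
    value = max(d for n, d in depths.items() if n.is_tip or n is anc)
    return MashValue(clade.name, value, tree_id)


def mash_table(trees: dict, clades) -> pd.DataFrame:
    """MaSH values for each clade (rows) on each tree (columns).

    Clades whose tips are not all present in a given tree get ``NaN`` in that
    cell (rendered as ``~`` by :func:`write_mash_table`).  Rows are sorted in
    ascending order of the first tree's value.
    """
    clades = list(clades)
    if not clades:
        raise TreeError("no clades given")
    data = {}
    for tree_id, tree in trees.items():
        col = {}
        tip_set = set(tree.tip_labels())
        for clade in clades:
            if set(clade.tips) <= tip_set:
                col[clade.name] = mash(tree, clade, tree_id).value
            else:
                col[clade.name] = float("nan")
        data[tree_id] = col
    df = pd.DataFrame(data, index=[c.name for c in clades])
    first = df.columns[0]
    return df.sort_values(first, kind="stable")


def write_mash_table(df: pd.DataFrame, path_or_buf) -> None:
    """Write a MaSH table as TSV, with ``~`` for unavailable cells."""
    out = df.copy()
    text = out.to_csv(sep="\t", float_format="%.6g", na_rep="~")
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_clade_specs(path) -> list:
    """Read clade specs from TSV: ``name<TAB>tip1,tip2,...`` per line."""
    specs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, tips = line.split("\t", 1)
            specs.append(CladeSpec(name, {t.strip() for t in tips.split(",")}))
    return specs
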