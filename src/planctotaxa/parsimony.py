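"""Fitch parsimony: minimum numbers of state changes on a fixed topology.

The Fitch algorithm computes, per alignment column, the minimum number of
substitutions needed to explain the observed tip states on a given tree under
unordered (any-to-any) changes.  Totals feed maximum-parsimony tree choice;
per-site step vectors feed the parsimony variant of the paired-site
Kishino–Hasegawa test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqmodels import Alignment, _check_labels
from .trees import Node, PhyloTree

__all__ = ["ParsimonyScore", "fitch_score", "per_site_step_difference"]

# IUPAC -> bitmask over (A=1, C=2, G=4, T=8)
_BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8, "U": 8,
    "R": 5, "Y": 10, "S": 6, "W": 9, "K": 12, "M": 3,
    "B": 14, "D": 13, "H": 11, "V": 7,
    "N": 15, "?": 15, "-": 15, ".": 15,
}
_GAP_AS_STATE = dict(_BITS, **{"-": 16, ".": 16})
_RY_BITS = {"R": 1, "Y": 2, "-": 3, "?": 3, ".": 3, "N": 3}


@dataclass(frozen=True)
class ParsimonyScore:
    per_site_steps: np.ndarray
    total: int = 0

    def __post_init__(self):
        steps = np.asarray(self.per_site_steps, dtype=int)
        object.__setattr__(self, "per_site_steps", steps)
        object.__setattr__(self, "total", int(steps.sum()))


def _encode(aln: Alignment, gap_as_state: bool) -> dict:
    if aln.alphabet == "ry":
        table = _RY_BITS
    else:
        table = _GAP_AS_STATE if gap_as_state else _BITS
    out = {}
    for label, seq in aln.sequences.items():
        try:
            out[label] = np.array([table[c] for c in seq], dtype=np.int64)
        except KeyError as exc:
            raise ValueError(f"unknown symbol {exc} in {label!r}") from None
    return out


def _binary_root(tree: PhyloTree) -> PhyloTree:
    """Resolve a trifurcating root into a zero-length bifurcation.

    Fitch scores are invariant to the rooting of the underlying unrooted
    tree, so this changes nothing but makes the bottom-up pass strictly
    binary at the root.
    """
    if len(tree.root.children) <= 2:
        return tree
    tree = tree.copy()
    while len(tree.root.children) > 2:
        a = tree.root.children.pop()
        b = tree.root.children.pop()
        joint = Node(None, 0.0)
        joint.add_child(a)
        joint.add_child(b)
        tree.root.add_child(joint)
    return tree


def fitch_score(aln: Alignment, tree: PhyloTree,
                gap_as_state: bool = False) -> ParsimonyScore:
    """Fitch parsimony steps per site and in total.

    Gaps and N are treated as missing data (the full state set) by default;
    with ``gap_as_state`` the gap becomes a fifth state.  The score does not
    depend on where the unrooted topology is rooted.
    """
    _check_labels(aln, tree)
    tree = _binary_root(tree)
    masks = _encode(aln, gap_as_state)
    steps = np.zeros(aln.length, dtype=np.int64)
    state: dict = {}
    for node in tree.postorder():
        if node.is_tip:
            state[node] = masks[node.label]
            continue
        acc = None
        for child in tree_children(node):
            m = state[child]
            if acc is None:
                acc = m
                continue
            inter = acc & m
            union = acc | m
            empty = inter == 0
            steps += empty
            acc = np.where(empty, union, inter)
        state[node] = acc
    return ParsimonyScore(steps)


def tree_children(node):
    return node.children


def per_site_step_difference(aln: Alignment, tree_a: PhyloTree,
                             tree_b: PhyloTree,
                             gap_as_state: bool = False) -> np.ndarray:
    """Per-site Fitch step difference, tree A minus tree B.

    The vector sums to the difference of the total scores; it is the paired
    per-site input of the parsimony Kishino–Hasegawa test.
    """
    sa = fitch_score(aln, tree_a, gap_as_state)
    sb = fitch_score(aln, tree_b, gap_as_state)
    return sa.per_site_steps - sb.per_site_steps
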