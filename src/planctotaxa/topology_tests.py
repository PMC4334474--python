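"""Topology enumeration, constrained searches, and paired-site tests.

When a classification asserts that named genera are monophyletic, the
assertion can be tested by comparing the best unconstrained tree with the
best tree found under a constraint forcing each genus to form a clade.  The
score difference is then assessed with paired-site tests on the per-site
log-likelihoods (or parsimony steps): the Kishino–Hasegawa (KH) test for a
pair of a-priori trees, and the Shimodaira–Hasegawa (SH) test, whose centered
resampling corrects for having selected the best tree from a candidate set.
Both use RELL resampling — bootstrapping per-site values without
re-optimizing model parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import parsimony as mp
from . import seqmodels as sq
from .trees import Node, PhyloTree, TreeError

__all__ = [
    "Constraint",
    "TestResult",
    "enumerate_topologies",
    "bipartitions",
    "satisfies_constraint",
    "best_tree",
    "exhaustive_comparison",
    "constrained_comparison",
    "kh_test",
    "sh_test",
    "bootstrap_support",
]

ENUMERATION_LIMIT = 10
DEFAULT_ENUMERATION_REFUSAL = 8


@dataclass(frozen=True)
class Constraint:
    """Backbone monophyly constraint: each listed group must form a clade.

    Groups must be pairwise disjoint or nested, each of size >= 2.
    """

    groups: tuple

    def __init__(self, groups):
        object.__setattr__(
            self, "groups", tuple(frozenset(g) for g in groups)
        )
        for g in self.groups:
            if len(g) < 2:
                raise TreeError("constraint groups need at least 2 tips")
        for a, b in itertools.combinations(self.groups, 2):
            if a & b and not (a <= b or b <= a):
                raise TreeError(
                    f"constraint groups overlap without nesting: "
                    f"{sorted(a)} / {sorted(b)}"
                )

    @classmethod
    def read(cls, path):
        """One group per line, comma-separated tip labels."""
        groups = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    groups.append({t.strip() for t in line.split(",")})
        return cls(groups)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a paired-site topology test."""

    statistic: float
    p_value: float
    alpha: float
    method: str  # KH-normal | KH-RELL | SH-RELL
    n_resamples: int
    seed: int | None = None
    label: str = ""

    @property
    def reject(self) -> bool:
        return self.p_value < self.alpha


# -- enumeration ----------------------------------------------------------------


def _leaf(label):
    return Node(label, 1.0)


def _clone(node):
    c = Node(node.label, node.length)
    for ch in node.children:
        c.add_child(_clone(ch))
    return c


def _edge_nodes(root):
    out = []
    stack = list(root.children)
    while stack:
        n = stack.pop()
        out.append(n)
        stack.extend(n.children)
    return out


def _insert_on_edge(root, edge_node, new_subtree):
    """Copy the tree, splitting the edge above ``edge_node`` with a new node."""
    mapping = {}

    def clone(node):
        c = Node(node.label, node.length)
        mapping[node] = c
        for ch in node.children:
            c.add_child(clone(ch))
        return c

    new_root = clone(root)
    target = mapping[edge_node]
    parent = target.parent
    parent.children.remove(target)
    joint = Node(None, 1.0)
    joint.add_child(target)
    joint.add_child(_clone(new_subtree))
    parent.add_child(joint)
    target.length = 1.0
    return new_root


def _enumerate_unrooted(subtrees):
    """All unrooted binary topologies whose leaves are the given subtrees.

    Subtrees are treated as atomic units: enumeration runs over placeholder
    leaves, which are grafted back afterwards, so no edge internal to a unit
    ever receives an insertion.
    """
    subtrees = list(subtrees)
    if len(subtrees) < 3:
        raise TreeError("need at least 3 units to enumerate unrooted trees")
    names = [f"\x01U{i}\x01" for i in range(len(subtrees))]
    base = Node(None, None)
    for name in names[:3]:
        base.add_child(_leaf(name))
    trees = [base]
    for name in names[3:]:
        nxt = []
        for t in trees:
            for edge in _edge_nodes(t):
                nxt.append(_insert_on_edge(t, edge, _leaf(name)))
        trees = nxt
    lookup = dict(zip(names, subtrees))
    return [_graft(t, lookup) for t in trees]


def _graft(root, lookup):
    """Replace placeholder leaves with clones of their subtrees."""
    sub = lookup.get(root.label)
    if sub is not None:
        clone = _clone(sub)
        clone.length = root.length
        return clone
    root.children = [_graft(c, lookup) for c in root.children]
    for c in root.children:
        c.parent = root
    return root


def _enumerate_rooted(subtrees):
    """All rooted binary topologies over the given subtrees."""
    subtrees = list(subtrees)
    if len(subtrees) == 1:
        return [_clone(subtrees[0])]
    from .trees import _adjacency, _rebuild_from

    dummy = _leaf("\x00ROOT\x00")
    out = []
    for t in _enumerate_unrooted(subtrees + [dummy]):
        # re-orient away from the dummy leaf; suppressing the resulting
        # unifurcation at the dummy drops it and leaves the binary root
        tree = PhyloTree(t)
        node = tree.node_for("\x00ROOT\x00")
        rooted = _rebuild_from(_adjacency(tree), node)
        sub = rooted.root
        assert sub.label != dummy.label and len(sub.children) == 2
        sub.length = 1.0
        out.append(sub)
    return out


def _group_subtrees(members, nested):
    """Rooted topologies for a constraint group, honoring nested groups."""
    top = _toplevel(nested)
    units = set(members)
    for g in top:
        units -= g
    unit_lists = []
    for g in top:
        inner = [h for h in nested if h < g]
        unit_lists.append(_group_subtrees(g, inner))
    fixed = [[_leaf(x)] for x in sorted(units)]
    out = []
    for combo in itertools.product(*(unit_lists + fixed)):
        out.extend(_enumerate_rooted(combo))
    return out


def _toplevel(groups):
    return [g for g in groups
            if not any(g < h for h in groups)]


def enumerate_topologies(tips, constraint: Constraint | None = None,
                         limit: int = DEFAULT_ENUMERATION_REFUSAL):
    """All distinct unrooted binary topologies on ``tips`` (unit lengths).

    With a constraint, only topologies in which every constrained group forms
    a clade are produced; these are generated directly (groups collapsed,
    then expanded), not by filtering.  The unconstrained count is
    (2n-5)!!, so enumeration refuses more than ``limit`` tips.
    """
    tips = sorted(tips)
    if len(tips) < 3:
        raise TreeError("need at least 3 tips")
    if len(set(tips)) != len(tips):
        raise TreeError("duplicate tip labels")
    if len(tips) > min(limit, ENUMERATION_LIMIT):
        raise TreeError(
            f"{len(tips)} tips exceeds the exhaustive enumeration limit "
            f"({min(limit, ENUMERATION_LIMIT)}); use an NNI search instead"
        )
    if constraint is None:
        constraint = Constraint(())
    tipset = set(tips)
    for g in constraint.groups:
        if not g <= tipset:
            raise TreeError(f"constraint group {sorted(g)} not a subset of tips")
    # a group containing every tip constrains nothing
    groups = [g for g in constraint.groups if g != frozenset(tipset)]
    top = _toplevel(groups)
    free = set(tips)
    for g in top:
        free -= g
    unit_lists = [
        _group_subtrees(g, [h for h in groups if h < g])
        for g in top
    ]
    unit_lists += [[_leaf(x)] for x in sorted(free)]
    for combo in itertools.product(*unit_lists):
        if len(combo) == 1:  # one constrained group covers every tip
            root = _clone(combo[0])
            root.length = None
            yield PhyloTree(root)
        elif len(combo) == 2:
            root = Node(None, None)
            root.add_child(_clone(combo[0]))
            root.add_child(_clone(combo[1]))
            yield PhyloTree(root)
        else:
            for root in _enumerate_unrooted(combo):
                yield PhyloTree(root)


def bipartitions(tree: PhyloTree):
    """Canonical non-trivial splits of an unrooted topology.

    Each split is the frozenset of tip labels on the side *not* containing
    the lexicographically smallest tip.
    """
    all_tips = frozenset(tree.tip_labels())
    anchor = min(all_tips)
    n = len(all_tips)
    splits = set()
    below = {}
    for node in tree.postorder():
        if node.is_tip:
            below[node] = frozenset([node.label])
            continue
        s = frozenset().union(*(below[c] for c in node.children))
        below[node] = s
        side = all_tips - s if anchor in s else s
        if 2 <= len(side) <= n - 2:
            splits.add(side)
    return frozenset(splits)


def satisfies_constraint(tree: PhyloTree, constraint: Constraint) -> bool:
    """Whether every constrained group is a clade of the unrooted topology."""
    n = len(tree.tip_labels())
    splits = bipartitions(tree)
    all_tips = frozenset(tree.tip_labels())
    anchor = min(all_tips)
    for g in constraint.groups:
        if len(g) in (1, n - 1, n):
            continue
        side = all_tips - g if anchor in g else frozenset(g)
        if side not in splits:
            return False
    return True


# -- tree search ----------------------------------------------------------------


def _score(tree, aln, model, criterion, optimize, tol):
    if criterion == "ML":
        if optimize:
            # search-grade settings: start every branch at 0.1 (much closer
            # to typical optima than the unit lengths the enumerator emits)
            # and use a coarse per-branch tolerance; stopping at the cycle
            # cap is routine here, not a failure worth a warning
            tree = tree.copy()
            for node in tree.postorder():
                if node is not tree.root:
                    node.length = 0.1
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore", UserWarning)
                tree = sq.optimize_branch_lengths(tree, aln, model, tol=tol,
                                                  max_cycles=4,
                                                  xatol=min(tol, 1e-3))
        return tree, sq.log_likelihood(aln, tree, model)
    if criterion == "MP":
        return tree, float(mp.fitch_score(aln, tree).total)
    raise ValueError(f"unknown criterion {criterion!r}")


def _better(criterion, a, b):
    return a > b if criterion == "ML" else a < b


def _nni_neighbors(tree: PhyloTree):
    """The two NNI rearrangements of every internal edge."""
    out = []
    nodes = [n for n in tree.postorder()
             if not n.is_tip and n.parent is not None]
    for node in nodes:
        parent = node.parent
        siblings = [c for c in parent.children if c is not node]
        for sib in siblings:
            for i in range(len(node.children)):
                t2 = tree.copy()
                # rebuild references in the copy by positional lookup
                path = _node_path(tree, node)
                node2 = _follow(t2, path)
                parent2 = node2.parent
                sib2 = _follow(t2, _node_path(tree, sib))
                child2 = node2.children[i]
                node2.children[i] = sib2
                parent2.children[parent2.children.index(sib2)] = child2
                sib2.parent, child2.parent = node2, parent2
                out.append(t2)
            break  # one sibling generates both distinct rearrangements
    return out


def _node_path(tree, node):
    path = []
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    return list(reversed(path))


def _follow(tree, path):
    node = tree.root
    for i in path:
        node = node.children[i]
    return node


def _start_tree(labels, rng):
    order = list(labels)
    rng.shuffle(order)
    root = Node(None, None)
    for x in order[:3]:
        root.add_child(_leaf(x))
    tree = root
    for x in order[3:]:
        edges = _edge_nodes(tree)
        tree = _insert_on_edge(tree, edges[rng.integers(len(edges))],
                               _leaf(x))
    return PhyloTree(tree)


def best_tree(aln, model=None, criterion: str = "ML",
              constraint: Constraint | None = None,
              search: str = "exhaustive", seed: int | None = None,
              optimize: bool = True, tol: float = 1e-3):
    """Best topology under ML or MP, optionally under a monophyly constraint.

    Exhaustive search enumerates every (constraint-compatible) topology; for
    ML each topology's branch lengths are optimized before scoring.  The NNI
    search climbs steepest-ascent from a random start, rejecting moves that
    violate the constraint.  Returns ``(tree, score)``; ties are broken by
    enumeration order, so results are deterministic.
    """
    labels = sorted(aln.labels)
    if model is None and criterion == "ML":
        model = sq.SubstitutionModel.jc69()
    if search == "exhaustive":
        best = None
        for topo in enumerate_topologies(labels, constraint):
            tree, score = _score(topo, aln, model, criterion, optimize, tol)
            if best is None or _better(criterion, score, best[1]):
                best = (tree, score)
        if best is None:
            raise TreeError("no topology satisfies the constraint")
        return best
    if search == "nni":
        rng = np.random.default_rng(seed)
        current = _start_tree(labels, rng)
        if constraint is not None and not satisfies_constraint(current, constraint):
            # rebuild from a constraint-compatible topology
            current = next(iter(enumerate_topologies(labels, constraint))) \
                if len(labels) <= ENUMERATION_LIMIT else current
        current, cur_score = _score(current, aln, model, criterion,
                                    optimize, tol)
        improved = True
        while improved:
            improved = False
            for nb in _nni_neighbors(current):
                if constraint is not None and not satisfies_constraint(nb, constraint):
                    continue
                cand, cand_score = _score(nb, aln, model, criterion,
                                          optimize, tol)
                if _better(criterion, cand_score, cur_score):
                    current, cur_score = cand, cand_score
                    improved = True
                    break
        return current, cur_score
    raise ValueError(f"unknown search {search!r}")


def exhaustive_comparison(aln, model=None, criterion: str = "ML",
                          constraints: dict | None = None,
                          optimize: bool = True, tol: float = 1e-3) -> dict:
    """Score every topology once; report the optimum under each constraint.

    ``constraints`` maps names to :class:`Constraint` objects.  Returns a
    dict with key ``"unconstrained"`` plus one key per constraint, each
    holding ``(tree, score)``.  Because all optima are maxima of the same
    score table, the restriction property (a constrained optimum never beats
    the unconstrained one, with equality whenever the unconstrained optimum
    already satisfies the constraint) holds exactly.
    """
    labels = sorted(aln.labels)
    if model is None and criterion == "ML":
        model = sq.SubstitutionModel.jc69()
    constraints = dict(constraints or {})
    best = {name: None for name in ("unconstrained", *constraints)}
    for topo in enumerate_topologies(labels):
        tree, score = _score(topo, aln, model, criterion, optimize, tol)
        for name in best:
            if name != "unconstrained" and not satisfies_constraint(
                    topo, constraints[name]):
                continue
            if best[name] is None or _better(criterion, score, best[name][1]):
                best[name] = (tree, score)
    for name, value in best.items():
        if value is None:
            raise TreeError(f"no topology satisfies constraint {name!r}")
    return best


def constrained_comparison(aln, model=None, criterion: str = "ML",
                           constraint: Constraint | None = None,
                           optimize: bool = True, tol: float = 1e-3):
    """Best unconstrained vs. best constraint-compatible tree, scored once.

    Returns ``(best_free, score_free, best_constrained, score_constrained)``.
    See :func:`exhaustive_comparison` for the guarantees.
    """
    result = exhaustive_comparison(
        aln, model, criterion,
        {"constrained": constraint or Constraint(())}, optimize, tol)
    free, con = result["unconstrained"], result["constrained"]
    return free[0], free[1], con[0], con[1]


# -- paired-site tests ----------------------------------------------------------


def _bootstrap_counts(rng, n, B):
    return rng.multinomial(n, np.full(n, 1.0 / n), size=B)


def kh_test(per_site_a, per_site_b, method: str = "RELL", B: int = 1000,
            seed: int | None = None, alpha: float = 0.05) -> TestResult:
    """Kishino–Hasegawa paired-site test of two a-priori topologies.

    Tests H0: E[delta] = 0 where delta_i is the per-site difference (log
    likelihood, or parsimony steps with the sign convention A - B).  The
    normal method uses a t statistic on the per-site differences; the RELL
    method resamples sites with replacement from the centered differences.
    Two-sided.
    """
    a = np.asarray(per_site_a, float)
    b = np.asarray(per_site_b, float)
    if a.shape != b.shape:
        raise ValueError("per-site vectors differ in length")
    delta = a - b
    statistic = float(delta.sum())
    n = delta.size
    if np.all(delta == 0):
        return TestResult(0.0, 1.0, alpha, f"KH-{method}", 0, seed)
    if method == "normal":
        sd = delta.std(ddof=1)
        t = delta.mean() / (sd / np.sqrt(n))
        p = float(2 * stats.t.sf(abs(t), n - 1))
        return TestResult(statistic, p, alpha, "KH-normal", 0, seed)
    if method == "RELL":
        if B < 100:
            raise ValueError("RELL needs at least 100 resamples")
        rng = np.random.default_rng(seed)
        centered = delta - delta.mean()
        sums = _bootstrap_counts(rng, n, B) @ centered
        p = float((np.count_nonzero(np.abs(sums) >= abs(statistic)) + 1)
                  / (B + 1))
        return TestResult(statistic, min(p, 1.0), alpha, "KH-RELL", B, seed)
    raise ValueError(f"unknown KH method {method!r}")


def sh_test(per_site_matrix, best_index: int | None = None, B: int = 1000,
            seed: int | None = None, alpha: float = 0.01,
            labels=None) -> list:
    """Shimodaira–Hasegawa test of each candidate tree against the best one.

    Rows of ``per_site_matrix`` are trees, columns are sites.  RELL
    resampling: per-tree centering of resampled totals accounts for the
    selection of the best tree; the p-value of tree t is the fraction of
    resamples in which the centered best-minus-t difference is at least the
    observed difference.  The best tree's p-value is 1 by construction, and
    no tree's p-value exceeds it.
    """
    M = np.asarray(per_site_matrix, float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a trees x sites matrix with at least 2 rows")
    if B < 100:
        raise ValueError("RELL needs at least 100 resamples")
    T, n = M.shape
    totals = M.sum(axis=1)
    if best_index is None:
        best_index = int(np.argmax(totals))
    observed = totals[best_index] - totals
    if observed.min() < -1e-9:
        raise ValueError("best_index does not have the highest total")
    rng = np.random.default_rng(seed)
    S = _bootstrap_counts(rng, n, B) @ M.T  # (B, T) resampled totals
    centered = S - S.mean(axis=0)
    D = centered.max(axis=1)[:, None] - centered  # (B, T)
    results = []
    for t in range(T):
        # the +1/(B+1) convention keeps the p-value valid at finite B;
        # the best tree still gets p = 1 (its observed difference is 0 and
        # every centered max-difference is >= 0)
        count = int(np.count_nonzero(D[:, t] >= observed[t] - 1e-12))
        p = (count + 1) / (B + 1)
        results.append(TestResult(
            float(observed[t]), p, alpha, "SH-RELL", B, seed,
            label=str(labels[t]) if labels is not None else str(t),
        ))
    return results


# -- bootstrap support ----------------------------------------------------------


def bootstrap_support(aln, criterion: str = "ML", B: int = 100,
                      seed: int | None = None, model=None,
                      constraint: Constraint | None = None,
                      search: str = "exhaustive") -> dict:
    """Nonparametric bootstrap support for bipartitions, in percent.

    Alignment columns are resampled with replacement; the best tree is
    re-estimated on each replicate; each bipartition's support is the
    percentage of replicates containing it.  Deterministic given the seed.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if aln.length < 2:
        raise ValueError("alignment too short to bootstrap")
    rng = np.random.default_rng(seed)
    counts: dict = {}
    for _ in range(B):
        idx = rng.integers(0, aln.length, size=aln.length)
        resampled = sq.Alignment(
            {lab: "".join(seq[i] for i in idx)
             for lab, seq in aln.sequences.items()},
            alphabet=aln.alphabet,
        )
        tree, _ = best_tree(resampled, model=model, criterion=criterion,
                            constraint=constraint, search=search,
                            seed=int(rng.integers(2 ** 31)),
                            optimize=(criterion == "ML"), tol=1e-2)
        for split in bipartitions(tree):
            counts[split] = counts.get(split, 0) + 1
    return {split: 100.0 * c / B for split, c in counts.items()}
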