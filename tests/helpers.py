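"""Independent oracles used by the tests.

These deliberately avoid the package's own algorithms: likelihoods by explicit
enumeration of internal states, parsimony by exhaustive minimization over
internal assignments, Ward clustering by greedy minimization of the
within-cluster variance increase.  They are only feasible at tiny sizes,
which is the point — the package is checked against them where enumeration
is possible.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from planctotaxa import seqmodels as sq


def brute_force_loglik(aln, tree, model):
    """Site likelihoods by explicit summation over internal-node states."""
    pi = np.asarray(model.base_frequencies, float)
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_tip]
    n_states = model.n_states
    states = model.states
    rates = model.category_rates()
    total = 0.0
    for site in range(aln.length):
        site_lik = 0.0
        for rate in rates:
            P = {
                n: sq.transition_probabilities(model, n.length * rate)
                for n in nodes if n is not tree.root
            }
            lik = 0.0
            for assign in itertools.product(range(n_states),
                                            repeat=len(internal)):
                amap = dict(zip(internal, assign))
                p = pi[amap[tree.root]]
                for n in nodes:
                    if n is tree.root:
                        continue
                    ps = amap[n.parent]
                    if n.is_tip:
                        ch = aln.sequences[n.label][site]
                        compat = [states.index(s) for s in sq.IUPAC[ch]
                                  if s in states]
                        p *= sum(P[n][ps, c] for c in compat)
                    else:
                        p *= P[n][ps, amap[n]]
                lik += p
            site_lik += lik / len(rates)
        total += math.log(site_lik)
    return total


def brute_force_fitch(aln, tree):
    """Minimum changes per site over all internal-node state assignments."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_tip]
    steps = []
    for site in range(aln.length):
        best = None
        tip_state = {
            n: "ACGT".index(aln.sequences[n.label][site])
            for n in nodes if n.is_tip
        }
        for assign in itertools.product(range(4), repeat=len(internal)):
            amap = dict(zip(internal, assign))
            amap.update(tip_state)
            changes = sum(
                amap[n] != amap[n.parent]
                for n in nodes if n is not tree.root
            )
            best = changes if best is None else min(best, changes)
        steps.append(best)
    return np.array(steps)


def ward_oracle_merges(X):
    """Greedy Ward agglomeration: merge the pair with the smallest increase
    in total within-cluster variance, lexicographic tie-break.

    Returns the same (a, b, new_id) merge sequence convention as
    :class:`planctotaxa.chemotax.Dendrogram` plus the variance increase of
    each merge.
    """
    X = np.asarray(X, float)
    n = X.shape[0]
    clusters = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            ma = X[clusters[a]].mean(axis=0)
            mb = X[clusters[b]].mean(axis=0)
            na, nb = len(clusters[a]), len(clusters[b])
            delta = na * nb / (na + nb) * ((ma - mb) ** 2).sum()
            key = (delta, (a, b))
            if best is None or key < best[0]:
                best = (key, a, b)
        (_, _), a, b = best[0], best[1], best[2]
        delta = best[0][0]
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        merges.append((a, b, delta, next_id))
        next_id += 1
    return merges


def tip_depths(tree):
    """Root-to-tip path lengths by label."""
    out = {}

    def walk(node, depth):
        for child in node.children:
            d = depth + child.length
            if child.is_tip:
                out[child.label] = d
            else:
                walk(child, d)

    walk(tree.root, 0.0)
    return out
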