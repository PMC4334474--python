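"""Nucleotide alignments, substitution models and tree likelihoods.

Implements the likelihood machinery behind maximum-likelihood tree scoring:
time-reversible substitution models (JC69, HKY85, GTR) with optional
discrete-gamma among-site rate variation, per-site log-likelihoods by the
pruning (sum-product) recursion with per-node numerical rescaling, and
coordinate-wise branch-length optimization on a fixed topology.  Per-site
log-likelihoods are the raw input of the paired-site topology tests in
:mod:`planctotaxa.topology_tests`.

Alignments may also be recoded to purines/pyrimidines (R/Y), a 2-state
alphabet that removes most base-compositional bias from deep divergences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from scipy.optimize import minimize_scalar
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .trees import PhyloTree, TreeError

__all__ = [
    "Alignment",
    "SubstitutionModel",
    "SiteLogLikelihoods",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "ry_recode",
    "gamma_category_rates",
    "transition_probabilities",
    "site_log_likelihoods",
    "log_likelihood",
    "optimize_branch_lengths",
]

DNA_STATES = "ACGT"
RY_STATES = "RY"

# IUPAC nucleotide ambiguity -> set of compatible ACGT states
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "?": "ACGT", "-": "ACGT", ".": "ACGT",
}


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True, eq=False)  # identity-hashed: used as a cache key
class Alignment:
    """Equal-length sequences over a DNA or RY alphabet."""

    sequences: dict
    alphabet: str = "dna"  # "dna" | "ry"

    def __post_init__(self):
        if not self.sequences:
            raise AlignmentError("empty alignment")
        lengths = {k: len(v) for k, v in self.sequences.items()}
        if len(set(lengths.values())) != 1:
            ragged = sorted(lengths.items(), key=lambda kv: kv[1])
            raise AlignmentError(f"ragged sequence lengths: {ragged}")
        if self.alphabet not in ("dna", "ry"):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def labels(self) -> list:
        return list(self.sequences)

    def __len__(self) -> int:
        return self.length


def read_fasta_alignment(path) -> Alignment:
    """Read an aligned FASTA file; residues are uppercased."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return Alignment(records)


def write_fasta_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for label, seq in aln.sequences.items():
            fh.write(f">{label}\n{seq}\n")


def ry_recode(aln: Alignment) -> Alignment:
    """Recode a DNA alignment to purine/pyrimidine (R/Y) states.

    A,G -> R and C,T -> Y.  Gaps are preserved; every ambiguity code that does
    not resolve within the purines or within the pyrimidines becomes missing
    ('?').
    """
    if aln.alphabet == "ry":
        raise AlignmentError("alignment is already RY-coded")
    table = {}
    for code, states in IUPAC.items():
        if code in "-.":
            table[code] = "-"
        elif set(states) <= set("AG"):
            table[code] = "R"
        elif set(states) <= set("CT"):
            table[code] = "Y"
        else:
            table[code] = "?"
    recoded = {
        label: "".join(table.get(ch, "?") for ch in seq)
        for label, seq in aln.sequences.items()
    }
    return Alignment(recoded, alphabet="ry")


# -- substitution models --------------------------------------------------------


@dataclass(frozen=True)
class SubstitutionModel:
    """Time-reversible substitution model with optional discrete-gamma rates.

    ``exchangeabilities`` are the six GTR rates in the order
    (AC, AG, AT, CG, CT, GT); for the 2-state RY alphabet a single value.  The
    rate matrix is scaled so the mean substitution rate at stationarity is 1,
    making branch lengths expected substitutions per site.
    """

    exchangeabilities: tuple = (1.0,) * 6
    base_frequencies: tuple = (0.25,) * 4
    gamma_shape: float | None = None
    n_rate_categories: int = 4

    def __post_init__(self):
        freqs = np.asarray(self.base_frequencies, float)
        if abs(freqs.sum() - 1.0) > 1e-12:
            raise ValueError("base frequencies must sum to 1")
        n = len(freqs)
        n_ex = n * (n - 1) // 2
        if len(self.exchangeabilities) != n_ex:
            raise ValueError(
                f"{n_ex} exchangeabilities required for {n} states, "
                f"got {len(self.exchangeabilities)}"
            )
        if any(x < 0 for x in self.exchangeabilities):
            raise ValueError("exchangeabilities must be non-negative")
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_rate_categories < 1:
            raise ValueError("need at least one rate category")

    @classmethod
    def jc69(cls, gamma_shape=None, n_rate_categories=4):
        return cls((1.0,) * 6, (0.25,) * 4, gamma_shape, n_rate_categories)

    @classmethod
    def hky85(cls, kappa, base_frequencies, gamma_shape=None,
              n_rate_categories=4):
        # transitions AG and CT get kappa
        return cls((1.0, kappa, 1.0, 1.0, kappa, 1.0),
                   tuple(base_frequencies), gamma_shape, n_rate_categories)

    @classmethod
    def gtr(cls, exchangeabilities, base_frequencies, gamma_shape=None,
            n_rate_categories=4):
        return cls(tuple(exchangeabilities), tuple(base_frequencies),
                   gamma_shape, n_rate_categories)

    @classmethod
    def ry_symmetric(cls, base_frequencies=(0.5, 0.5), gamma_shape=None,
                     n_rate_categories=4):
        """Two-state model for RY-coded data."""
        return cls((1.0,), tuple(base_frequencies), gamma_shape,
                   n_rate_categories)

    @property
    def n_states(self) -> int:
        return len(self.base_frequencies)

    @property
    def states(self) -> str:
        return DNA_STATES if self.n_states == 4 else RY_STATES

    def rate_matrix(self) -> np.ndarray:
        """Q with rows summing to 0, scaled to mean rate 1."""
        n = self.n_states
        pi = np.asarray(self.base_frequencies, float)
        Q = np.zeros((n, n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                s = self.exchangeabilities[k]
                Q[i, j] = s * pi[j]
                Q[j, i] = s * pi[i]
                k += 1
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        if mu <= 0:
            raise ValueError("degenerate rate matrix (all rates zero)")
        return Q / mu

    def eigensystem(self):
        """Eigendecomposition of Q via pi-symmetrization (cached)."""
        cached = _EIG_CACHE.get(id(self))
        if cached is None:
            pi = np.asarray(self.base_frequencies, float)
            sp = np.sqrt(pi)
            B = self.rate_matrix() * sp[:, None] / sp[None, :]
            B = (B + B.T) / 2.0
            w, V = np.linalg.eigh(B)
            left = V.T * sp[None, :]        # V' diag(sqrt pi)
            right = V / sp[:, None]         # diag(1/sqrt pi) V
            cached = (w, right, left)
            _EIG_CACHE[id(self)] = cached
            _EIG_KEEPALIVE.append(self)
        return cached

    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return gamma_category_rates(self.gamma_shape, self.n_rate_categories)


_EIG_CACHE: dict = {}
_EIG_KEEPALIVE: list = []


def read_model_config(path) -> SubstitutionModel:
    """Build a model from a flat key=value file.

    Recognized keys: ``model`` (JC|HKY|GTR|RY), ``kappa``, ``gamma_shape``,
    ``gamma_categories``, ``base_frequencies`` and ``exchangeabilities``
    (comma-separated).  Unknown keys are rejected.
    """
    cfg = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            cfg[key.strip().lower()] = value.strip()
    known = {"model", "kappa", "gamma_shape", "gamma_categories",
             "base_frequencies", "exchangeabilities"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown model config keys: {sorted(unknown)}")
    name = cfg.get("model", "GTR").upper()
    shape = float(cfg["gamma_shape"]) if "gamma_shape" in cfg else None
    k = int(cfg.get("gamma_categories", 4))
    freqs = tuple(float(x) for x in
                  cfg.get("base_frequencies", "0.25,0.25,0.25,0.25").split(","))
    if name == "JC":
        return SubstitutionModel.jc69(shape, k)
    if name == "HKY":
        return SubstitutionModel.hky85(float(cfg.get("kappa", 2.0)),
                                       freqs, shape, k)
    if name == "GTR":
        ex = tuple(float(x) for x in
                   cfg.get("exchangeabilities", "1,1,1,1,1,1").split(","))
        return SubstitutionModel.gtr(ex, freqs, shape, k)
    if name == "RY":
        ry_freqs = freqs if len(freqs) == 2 else (0.5, 0.5)
        return SubstitutionModel.ry_symmetric(ry_freqs, shape, k)
    raise ValueError(f"unknown model {name!r}")


def gamma_category_rates(shape: float, k: int) -> np.ndarray:
    """Mean rates of k equal-probability categories of a Gamma(shape, mean 1).

    Category boundaries are the i/k quantiles; the rate of each category is
    the conditional mean of the distribution within the category (the
    mean-of-quantiles discretization), so the rates average exactly to 1.
    """
    if k == 1:
        return np.ones(1)
    bounds = gamma_dist.ppf(np.arange(1, k) / k, shape, scale=1.0 / shape)
    upper = np.concatenate([bounds, [np.inf]])
    lower = np.concatenate([[0.0], bounds])
    # partial expectation of Gamma(a, rate=a) on [0, x] is gammainc(a+1, a*x)
    part = gammainc(shape + 1, shape * upper) - gammainc(shape + 1, shape * lower)
    return k * part


def transition_probabilities(model: SubstitutionModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt): probability of state j after time t given state i."""
    if t < 0:
        raise ValueError(f"negative branch length {t}")
    w, right, left = model.eigensystem()
    P = (right * np.exp(w * t)) @ left
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# -- likelihood -----------------------------------------------------------------


@dataclass(frozen=True)
class SiteLogLikelihoods:
    per_site: np.ndarray
    total: float = field(default=None)

    def __post_init__(self):
        object.__setattr__(self, "per_site", np.asarray(self.per_site, float))
        object.__setattr__(self, "total", float(self.per_site.sum()))


def _tip_partials(seq: str, states: str) -> np.ndarray:
    """Partial likelihoods at a tip: 1 for each state compatible with the symbol."""
    n = len(states)
    out = np.zeros((len(seq), n))
    for i, ch in enumerate(seq):
        if n == 4:
            compat = IUPAC.get(ch)
            if compat is None:
                raise AlignmentError(f"unknown symbol {ch!r}")
            for s in compat:
                out[i, states.index(s)] = 1.0
        else:  # RY
            if ch == "R":
                out[i, 0] = 1.0
            elif ch == "Y":
                out[i, 1] = 1.0
            else:  # gap / missing
                out[i, :] = 1.0
    return out


def _check_labels(aln: Alignment, tree: PhyloTree):
    a, t = set(aln.labels), set(tree.tip_labels())
    if a != t:
        diff = sorted(a.symmetric_difference(t))
        raise TreeError(f"alignment/tree label mismatch: {diff}")


_PATTERN_CACHE: dict = {}


def _pattern_compress(aln: Alignment, labels, states: str):
    """Unique site patterns with tip partials, cached per alignment object.

    Tree searches score one alignment against thousands of topologies; the
    pattern compression and tip partial-likelihood encodings depend only on
    the alignment, so they are computed once.
    """
    key = (id(aln), tuple(labels), states)
    hit = _PATTERN_CACHE.get(key)
    if hit is not None and hit[0]() is aln:
        return hit[1], hit[2]
    cols = np.array([list(aln.sequences[x]) for x in labels])
    patterns, inverse = np.unique(cols, axis=1, return_inverse=True)
    tip_partials = {
        lab: _tip_partials("".join(patterns[i]), states)
        for i, lab in enumerate(labels)
    }
    import weakref

    if len(_PATTERN_CACHE) > 64:
        _PATTERN_CACHE.clear()
    _PATTERN_CACHE[key] = (weakref.ref(aln), tip_partials, inverse)
    return tip_partials, inverse


def site_log_likelihoods(aln: Alignment, tree: PhyloTree,
                         model: SubstitutionModel) -> SiteLogLikelihoods:
    """Per-site log-likelihoods by the pruning recursion.

    Gamma rate categories are averaged with equal weights.  Gaps and
    ambiguity codes contribute partial likelihood 1 over their compatible
    states.  Underflow is prevented by per-node rescaling with the scale
    factors accumulated in log space.
    """
    _check_labels(aln, tree)
    tree.require_branch_lengths()
    states = model.states
    if (model.n_states == 2) != (aln.alphabet == "ry"):
        raise AlignmentError("model alphabet does not match alignment alphabet")

    labels = tree.tip_labels()
    tip_partials, inverse = _pattern_compress(aln, labels, states)
    n_pat = next(iter(tip_partials.values())).shape[0]

    pi = np.asarray(model.base_frequencies, float)
    rates = model.category_rates()
    site_lik = np.zeros(n_pat)
    for rate in rates:
        partial, logscale = _prune(tree, tip_partials, model, rate)
        lik = partial @ pi
        site_lik += np.exp(np.log(np.maximum(lik, 1e-300)) + logscale)
    site_lik /= len(rates)
    per_site = np.log(site_lik)[inverse]
    return SiteLogLikelihoods(per_site)


def _prune(tree, tip_partials, model, rate):
    """Postorder pass; returns (root partials, per-pattern log scale)."""
    partials = {}
    scales = {}
    for node in tree.postorder():
        if node.is_tip:
            partials[node] = tip_partials[node.label]
            scales[node] = 0.0
            continue
        prod = None
        logscale = 0.0
        for child in node.children:
            P = transition_probabilities(model, child.length * rate)
            term = partials[child] @ P.T
            prod = term if prod is None else prod * term
            logscale = logscale + scales[child]
        mx = prod.max(axis=1)
        mx = np.maximum(mx, 1e-300)
        prod = prod / mx[:, None]
        partials[node] = prod
        scales[node] = logscale + np.log(mx)
    return partials[tree.root], scales[tree.root]


def log_likelihood(aln: Alignment, tree: PhyloTree,
                   model: SubstitutionModel) -> float:
    return site_log_likelihoods(aln, tree, model).total


def optimize_branch_lengths(tree: PhyloTree, aln: Alignment,
                            model: SubstitutionModel, tol: float = 1e-6,
                            max_cycles: int = 20,
                            bounds=(1e-9, 10.0),
                            xatol: float = 1e-8) -> PhyloTree:
    """Optimize branch lengths one at a time on a fixed topology.

    Cycles over branches, maximizing the total log-likelihood in each branch
    by bounded scalar search, until a full cycle improves the log-likelihood
    by less than ``tol``.  The returned tree's likelihood never falls below
    the input tree's.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    tree = tree.copy()
    tree.require_branch_lengths()
    branches = [n for n in tree.postorder() if n is not tree.root]
    current = log_likelihood(aln, tree, model)
    for _ in range(max_cycles):
        previous = current
        for node in branches:
            original = node.length

            def neg(t, node=node):
                node.length = t
                return -log_likelihood(aln, tree, model)

            res = minimize_scalar(neg, bounds=bounds, method="bounded",
                                  options={"xatol": xatol})
            if -res.fun >= current:
                node.length = float(res.x)
                current = -res.fun
            else:
                node.length = original
        if current - previous < tol:
            return tree
    warnings.warn("branch-length optimization did not converge; "
                  "returning best tree so far")
    return tree
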