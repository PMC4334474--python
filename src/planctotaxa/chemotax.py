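"""Chemotaxonomic profile analysis: fatty acids, polyamines and polar lipids.

Fatty-acid profiles are compositional (percentages of total fatty acids), so
before clustering they are variance-stabilized with the arcsine-square-root
transform, y = arcsin(sqrt(x/100)).  Profiles whose percentages do not add
up to roughly 100% indicate missing or overstated measurements and are
flagged (the default tolerance is five percentage points).  Transformed
profiles are grouped by agglomerative Ward clustering, which at every step
merges the pair of clusters whose fusion least increases the total
within-cluster variance.

Discrete traits (polyamines, polar lipids) are three-valued — present,
absent, or not reported — and taxon pairs are compared only over traits
reported for both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "TraitMatrix",
    "Dendrogram",
    "read_profiles",
    "read_traits",
    "sum_deviation_flags",
    "asin_sqrt_transform",
    "ward_cluster",
    "trait_difference",
]


@dataclass(frozen=True)
class ProfileMatrix:
    """Fatty-acid percentage measurements: rows are (taxon, source) records."""

    data: pd.DataFrame  # float values in [0, 100], NaN = missing

    def __post_init__(self):
        df = self.data
        if (df.to_numpy(float) < -1e-12).any():
            raise ValueError("negative percentages in profile matrix")

    @property
    def row_labels(self) -> list:
        return list(self.data.index)


def read_profiles(path) -> ProfileMatrix:
    """TSV with a ``taxon`` and ``source`` column, then fatty-acid columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.set_index(["taxon", "source"])
    return ProfileMatrix(df.astype(float))


def sum_deviation_flags(m: ProfileMatrix, threshold: float = 5.0) -> pd.Series:
    """Rows whose percentages sum more than ``threshold`` points from 100.

    Missing values count as zero, so a profile with many unreported minor
    acids will be flagged — which is the point: its percentages cannot be
    compared at face value with complete profiles.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = m.data.to_numpy(float)
    sums = np.nansum(values, axis=1)
    empty = np.all(np.isnan(values), axis=1)
    flags = (np.abs(sums - 100.0) > threshold) | empty
    return pd.Series(flags, index=m.data.index, name="flagged")


def asin_sqrt_transform(m: ProfileMatrix) -> pd.DataFrame:
    """Arcsine-square-root transform of percentages: arcsin(sqrt(x/100)).

    Maps 0 -> 0 and 100 -> pi/2 (radians); strictly monotone in between;
    missing values propagate.
    """
    values = m.data.to_numpy(float)
    bad = (values < 0) | (values > 100)
    if np.any(bad & ~np.isnan(values)):
        i, j = np.argwhere(bad & ~np.isnan(values))[0]
        raise ValueError(
            f"value {values[i, j]} outside [0, 100] at row "
            f"{m.data.index[i]}, column {m.data.columns[j]!r}"
        )
    return pd.DataFrame(np.arcsin(np.sqrt(values / 100.0)),
                        index=m.data.index, columns=m.data.columns)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration sequence of a hierarchical clustering.

    ``merges`` is a list of (cluster_a, cluster_b, height, new_cluster)
    with original rows numbered 0..n-1 and merged clusters n, n+1, ...
    (the scipy linkage convention); heights are non-decreasing for Ward.
    """

    merges: tuple
    labels: tuple

    @property
    def linkage(self) -> np.ndarray:
        """Scipy-style (n-1) x 4 linkage matrix."""
        n = len(self.labels)
        sizes = {i: 1 for i in range(n)}
        rows = []
        for a, b, h, new in self.merges:
            size = sizes[a] + sizes[b]
            sizes[new] = size
            rows.append([a, b, h, size])
        return np.array(rows, float)

    @property
    def leaf_order(self) -> list:
        """Left-to-right leaf order implied by the merge sequence."""
        n = len(self.labels)
        trees = {i: [i] for i in range(n)}
        for a, b, _, new in self.merges:
            trees[new] = trees.pop(a) + trees.pop(b)
        (order,) = trees.values()
        return [self.labels[i] for i in order]


def ward_cluster(matrix, labels=None, impute: str = "zero") -> Dendrogram:
    """Ward agglomeration of rows on Euclidean distances.

    Uses the Lance–Williams recurrence on squared Euclidean distances (the
    ward.D2 convention); reported heights are the square roots, matching
    scipy's ``linkage(method="ward")``.  Ties are broken by the
    lexicographically smallest cluster-index pair, so the merge sequence is
    deterministic.  Missing values are imputed as zero ("a trace below
    detection") by default, or by the row mean with ``impute="mean"``;
    all-missing rows are excluded with a warning.
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = list(matrix.index)
        matrix = matrix.to_numpy(float)
    X = np.array(matrix, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a matrix with at least 2 rows")
    if labels is None:
        labels = list(range(X.shape[0]))
    all_missing = np.all(np.isnan(X), axis=1)
    if all_missing.any():
        dropped = [labels[i] for i in np.nonzero(all_missing)[0]]
        warnings.warn(f"excluding all-missing rows: {dropped}")
        X = X[~all_missing]
        labels = [l for l, m in zip(labels, all_missing) if not m]
    if np.isnan(X).any():
        if impute == "zero":
            X = np.nan_to_num(X, nan=0.0)
        elif impute == "mean":
            row_means = np.nanmean(X, axis=1)
            idx = np.nonzero(np.isnan(X))
            X[idx] = row_means[idx[0]]
        else:
            raise ValueError(f"unknown imputation {impute!r}")

    n = X.shape[0]
    # squared Euclidean distances between active clusters
    sq = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = sq[i, j]
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    next_id = n
    for _ in range(n - 1):
        (i, j) = min(dist, key=lambda k: (dist[k], k))
        height = np.sqrt(dist[(i, j)])
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        active -= {i, j}
        for k in sorted(active):
            dik = dist.pop(tuple(sorted((i, k))))
            djk = dist.pop(tuple(sorted((j, k))))
            nk = sizes[k]
            dist[(k, new)] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dist[(i, j)]
            ) / (ni + nj + nk)
        del dist[(i, j)]
        sizes[new] = ni + nj
        active.add(new)
        merges.append((i, j, float(height), new))
    return Dendrogram(tuple(merges), tuple(labels))


def plot_heatmap(m: ProfileMatrix, path=None, flag_threshold: float = 5.0):
    """Clustered heat map of transformed profiles (thin optional layer).

    Rows follow the Ward leaf order; rows whose raw percentages sum more
    than ``flag_threshold`` points from 100 are marked with an asterisk.
    Returns the matplotlib figure; saves to ``path`` if given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    transformed = asin_sqrt_transform(m)
    dendro = ward_cluster(transformed)
    flags = sum_deviation_flags(m, flag_threshold)
    ordered = transformed.loc[dendro.leaf_order]
    fig, ax = plt.subplots(
        figsize=(1 + 0.4 * ordered.shape[1], 1 + 0.3 * ordered.shape[0]))
    im = ax.imshow(np.nan_to_num(ordered.to_numpy(), nan=0.0),
                   aspect="auto", cmap="viridis")
    ax.set_xticks(range(ordered.shape[1]),
                  labels=ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(ordered.shape[0]), labels=[
        f"{' / '.join(map(str, idx)) if isinstance(idx, tuple) else idx}"
        f"{' *' if flags.loc[idx] else ''}"
        for idx in ordered.index
    ], fontsize=7)
    fig.colorbar(im, ax=ax, label="arcsin sqrt(%/100)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig


# -- discrete traits ------------------------------------------------------------


@dataclass(frozen=True)
class TraitMatrix:
    """Present/absent/not-reported traits per taxon."""

    data: pd.DataFrame  # values "+", "-", "NR"

    def __post_init__(self):
        bad = ~self.data.isin(["+", "-", "NR"])
        if bad.to_numpy().any():
            cell = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"trait values must be +, - or NR; offending cell "
                f"({self.data.index[cell[0]]}, {self.data.columns[cell[1]]})"
            )

    @property
    def taxa(self) -> list:
        return list(self.data.index)


def read_traits(path=None) -> TraitMatrix:
    """Read a +/-/NR trait TSV (default: the bundled Planctomycetaceae
    polyamine and polar-lipid table)."""
    if path is None:
        from importlib import resources

        ref = resources.files("planctotaxa.data") / "planctomycetaceae_traits.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", index_col="taxon", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", index_col="taxon", comment="#")
    return TraitMatrix(df.astype(str))


def trait_difference(t: TraitMatrix, a: str, b: str):
    """Count trait disagreements between two taxa over comparable traits.

    Only traits reported (+ or -) for both taxa are compared.  Returns
    ``(n_differing, n_comparable, differing_traits)``.
    """
    for taxon in (a, b):
        if taxon not in t.data.index:
            raise ValueError(f"unknown taxon {taxon!r}")
    row_a, row_b = t.data.loc[a], t.data.loc[b]
    comparable = (row_a != "NR") & (row_b != "NR")
    if not comparable.any():
        raise ValueError(f"no comparable traits between {a!r} and {b!r}")
    differing = comparable & (row_a != row_b)
    return (
        int(differing.sum()),
        int(comparable.sum()),
        list(t.data.columns[differing]),
    )
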