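"""Sample-by-sample comparison of coverage and abundance profiles.

Coverage-profile resemblance uses Pearson correlation of binned median
depths (distance 1 - r), average-linkage clustering with optimal leaf
ordering. Community composition uses square-root transformed relative
abundances, Bray-Curtis dissimilarity, UPGMA trees, and non-metric
multidimensional scaling (Kruskal stress-1, SMACOF majorization with
isotonic regression, best of seeded restarts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "AbundanceTable",
    "DistanceMatrix",
    "Dendrogram",
    "OrdinationResult",
    "RegressionFit",
    "abundance_from_contigs",
    "coverage_correlation",
    "hcluster_olo",
    "bray_curtis",
    "bray_curtis_upgma",
    "nmds",
    "replicon_structure_fit",
]


@dataclass
class AbundanceTable:
    """Relative species abundances (%) per sample; each row sums to 100."""

    values: pd.DataFrame  # index = samples, columns = taxa

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if np.any(v < 0):
            raise ValueError("abundances must be >= 0")
        sums = v.sum(axis=1)
        if not np.allclose(sums, 100.0, atol=1e-6):
            raise ValueError("each sample's abundances must sum to 100")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-10):
            raise ValueError("diagonal must be zero")

    @property
    def condensed(self) -> np.ndarray:
        return squareform(self.d, checks=False)


@dataclass
class Dendrogram:
    """An agglomerative tree (scipy linkage matrix) with a leaf order."""

    linkage: np.ndarray
    labels: list[str]
    leaf_order: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> dict[str, int]:
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights
        (leaf branch = height of its first merge; ultrametric for UPGMA)."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            if node.is_leaf():
                name = self.labels[node.id]
                return f"{name}:{parent_height:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{max(parent_height - node.dist, 0.0):.6g}"

        root = tree
        inner = f"({walk(root.left, root.dist)},{walk(root.right, root.dist)});"
        return inner


@dataclass
class OrdinationResult:
    coords: np.ndarray  # samples x dims, centred at the origin
    stress: float
    seed: int
    labels: list[str] = field(default_factory=list)
    stress_history: list[float] = field(default_factory=list)


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r2: float


# ---------------------------------------------------------------------------


def abundance_from_contigs(contig_table: pd.DataFrame) -> AbundanceTable:
    """Build a relative abundance table from per-contig coverages.

    `contig_table` needs columns ``sample, fraction, taxon, coverage`` (one
    row per contig; `fraction` is the filter fraction the contig's assembly
    came from). Per fraction, a species' abundance is the sum of its contig
    coverages; per sample, fraction abundances are averaged; the result is
    normalised to % of the sample total.
    """
    required = {"sample", "fraction", "taxon", "coverage"}
    if not required.issubset(contig_table.columns):
        raise ValueError(f"contig_table needs columns {sorted(required)}")
    per_fraction = (
        contig_table.groupby(["sample", "fraction", "taxon"], sort=True)["coverage"]
        .sum()
        .unstack("taxon", fill_value=0.0)
    )
    per_sample = per_fraction.groupby(level="sample").mean()
    totals = per_sample.sum(axis=1)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total abundance")
    pct = per_sample.div(totals, axis=0) * 100.0
    return AbundanceTable(pct)


def coverage_correlation(binned: pd.DataFrame, method: str = "pearson") -> DistanceMatrix:
    """Distance 1 - r between samples' binned median coverage profiles
    (rows = samples, columns = bins)."""
    if binned.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    v = binned.to_numpy(dtype=float)
    sd = v.std(axis=1)
    if np.any(sd == 0):
        bad = binned.index[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"correlation undefined for constant sample {bad!r}")
    corr = binned.T.corr(method=method).to_numpy()
    d = np.clip(1.0 - corr, 0.0, None)  # guard fp error for r marginally > 1
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry
    return DistanceMatrix(list(binned.index), d)


def _optimal_leaf_order(Z: np.ndarray, d: np.ndarray) -> list[int]:
    """Exact optimal leaf ordering (Bar-Joseph dynamic programme).

    For every node, tabulate the cheapest ordering of its subtree for each
    (leftmost, rightmost) leaf pair; children may be swapped freely. Exact
    for any tree; cost is the sum of distances between adjacent leaves.
    O(n^3)-ish — fine for the tens of samples clustered here.
    """
    n = d.shape[0]
    M: dict[int, dict[tuple[int, int], tuple[float, tuple[int, ...]]]] = {
        i: {(i, i): (0.0, (i,))} for i in range(n)
    }
    for m, row in enumerate(Z):
        a, b = int(row[0]), int(row[1])
        table: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {}
        for left, right in ((a, b), (b, a)):
            for (l, ra), (ca, orda) in M[left].items():
                for (rb, r), (cb, ordb) in M[right].items():
                    cost = ca + cb + d[ra, rb]
                    key = (l, r)
                    if key not in table or cost < table[key][0]:
                        table[key] = (cost, orda + ordb)
        M[n + m] = table
        del M[a], M[b]
    (_, order) = min(M[n + len(Z) - 1].values())
    return list(order)


def hcluster_olo(dm: DistanceMatrix, method: str = "average") -> Dendrogram:
    """Average-linkage tree with optimal leaf ordering: among leaf orders
    consistent with the topology, the one minimising the sum of
    adjacent-leaf distances (exact dynamic programme)."""
    if len(dm.labels) < 2:
        raise ValueError("need >= 2 observations")
    cond = dm.condensed
    Z = hierarchy.linkage(cond, method=method)
    order = _optimal_leaf_order(Z, dm.d)
    return Dendrogram(Z, list(dm.labels), [dm.labels[i] for i in order])


def bray_curtis(table: AbundanceTable, transform: str = "sqrt") -> DistanceMatrix:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on (sqrt-transformed)
    relative abundances."""
    v = table.values.to_numpy(dtype=float)
    if transform == "sqrt":
        v = np.sqrt(v)
    elif transform is not None and transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    d = squareform(pdist(v, metric="braycurtis"))
    return DistanceMatrix(table.samples, d)


def bray_curtis_upgma(
    table: AbundanceTable, transform: str = "sqrt"
) -> tuple[DistanceMatrix, Dendrogram]:
    """Square-root transform, Bray-Curtis dissimilarity, UPGMA tree."""
    dm = bray_curtis(table, transform=transform)
    return dm, hcluster_olo(dm, method="average")


# ---------------------------------------------------------------------------
# non-metric MDS


def _stress1(dist: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(dist**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _smacof_single(
    d: np.ndarray, n: int, dims: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list[float]]:
    # primary tie approach: within tied dissimilarities, order by the current
    # configuration distances so equal d never forces equal disparities
    X = rng.uniform(-1, 1, size=(n, dims))
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    history: list[float] = []
    prev = np.inf
    i_idx, j_idx = np.triu_indices(n, k=1)
    for _ in range(max_iter):
        dist = np.sqrt(((X[i_idx] - X[j_idx]) ** 2).sum(axis=1))
        order = np.lexsort((dist, d))
        dhat = np.empty_like(dist)
        dhat[order] = iso.fit_transform(np.arange(order.size), dist[order])
        # scale disparities to the configuration scale
        scale = np.sqrt(np.sum(dist**2) / np.sum(dhat**2)) if np.sum(dhat**2) > 0 else 1.0
        dhat = dhat * scale
        stress = _stress1(dist, dhat)
        history.append(stress)
        if prev - stress < tol:
            break
        prev = stress
        # Guttman transform
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, dhat / dist, 0.0)
        B = np.zeros((n, n))
        B[i_idx, j_idx] = -ratio
        B[j_idx, i_idx] = -ratio
        B[np.diag_indices(n)] = -B.sum(axis=1)
        X = B @ X / n
        X -= X.mean(axis=0)
    X -= X.mean(axis=0)
    return X, history[-1], history


def nmds(
    dm: DistanceMatrix,
    dims: int = 2,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF majorization with isotonic regression.

    Runs `restarts` seeded random starts and keeps the configuration with
    the lowest Kruskal stress-1. Deterministic given `seed`. Coordinates are
    centred at the origin and rotated to principal axes.
    """
    n = len(dm.labels)
    if n < 4:
        raise ValueError("nMDS needs >= 4 observations")
    d = dm.condensed
    if np.any(~np.isfinite(d)):
        raise ValueError("distances must be finite")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, list[float]] | None = None
    for _ in range(restarts):
        X, stress, history = _smacof_single(d, n, dims, rng, max_iter, tol)
        if best is None or stress < best[1]:
            best = (X, stress, history)
    X, stress, history = best
    # rotate to principal axes for a canonical orientation
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    X = X @ vt.T
    return OrdinationResult(X, stress, seed, list(dm.labels), history)


def replicon_structure_fit(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    """OLS of the % of the primary replicon at low coverage (y) on the % of
    the genome held in secondary replicons (x)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need >= 3 (x, y) points")
    res = linregress(x, y)
    return RegressionFit(float(res.slope), float(res.intercept), float(res.rvalue**2))
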