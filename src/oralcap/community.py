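"""Cross-sample community structure statistics.

Covers the saliva-microbiome comparisons: a partition-around-medoids
silhouette scan over a range of cluster counts (to ask whether samples form
discrete clusters or a gradient), PCA loadings (which taxa drive the
gradient), a two-population comparison (per-taxon Wilcoxon rank-sum with
Bonferroni correction, plus the median/max "normalized relative abundance"
used for plotting), and Spearman correlation of abundance vectors (e.g.
capture-derived vs shotgun-derived estimates of the same community).

Compositional zeros are kept as true zeros — "effectively undetected"
reasoning depends on them — so no pseudocounts are added anywhere.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu, spearmanr
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

__all__ = [
    "AbundanceMatrix",
    "ClusterScan",
    "PopulationComparison",
    "silhouette_scan",
    "pam",
    "pca_loadings",
    "compare_populations",
    "abundance_correlation",
]


@dataclass(frozen=True)
class AbundanceMatrix:
    """Samples x taxa relative abundances (rows sum to 1)."""

    data: pd.DataFrame  # index = samples, columns = taxa
    level: str = "genus"
    populations: dict[str, str] | None = None  # sample -> population label

    def __post_init__(self):
        arr = self.data.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValueError("abundances must be >= 0")
        sums = arr.sum(axis=1)
        if len(arr) and np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("every sample's abundances must sum to 1")

    @property
    def n_samples(self) -> int:
        return len(self.data)


def _distance_matrix(matrix: AbundanceMatrix, distance: str) -> np.ndarray:
    x = matrix.data.to_numpy(dtype=float)
    if distance == "bray-curtis":
        return squareform(pdist(x, metric="braycurtis"))
    if distance == "euclidean":
        return squareform(pdist(x, metric="euclidean"))
    raise ValueError(f"unknown distance {distance!r}")


def pam(dist: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Partition around medoids on a precomputed distance matrix.

    Deterministic BUILD (greedy cost minimization) followed by SWAP passes
    until no swap lowers the total within-cluster distance.  Returns the
    medoid-index label per sample.
    """
    n = dist.shape[0]
    if not (2 <= k <= n - 1):
        raise ValueError(f"k={k} requires 2 <= k <= n-1 (n={n})")
    # BUILD
    medoids = [int(np.argmin(dist.sum(axis=0)))]
    while len(medoids) < k:
        current = np.min(dist[:, medoids], axis=1)
        gains = np.maximum(current[None, :] - dist, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids_arr = np.array(sorted(medoids))
    # SWAP
    def cost(meds: np.ndarray) -> float:
        return float(np.min(dist[:, meds], axis=1).sum())

    best_cost = cost(medoids_arr)
    for _ in range(max_iter):
        improved = False
        for mi in range(k):
            for h in range(n):
                if h in medoids_arr:
                    continue
                trial = medoids_arr.copy()
                trial[mi] = h
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost = c
                    medoids_arr = np.sort(trial)
                    improved = True
        if not improved:
            break
    labels = np.argmin(dist[:, medoids_arr], axis=1)
    return labels


@dataclass(frozen=True)
class ClusterScan:
    widths: dict[int, float]  # k -> average silhouette width (NaN if undefined)
    best_k: int | None
    best_width: float


def silhouette_scan(
    matrix: AbundanceMatrix,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    distance: str = "bray-curtis",
    seed: int = 0,
) -> ClusterScan:
    """Average silhouette width of a PAM partition for each candidate k.

    ``best_k`` maximizes the width.  When all pairwise distances are zero
    the silhouette is undefined: widths come back NaN with a warning and
    ``best_k`` is None.  ``seed`` is accepted for interface stability; the
    PAM implementation is fully deterministic.
    """
    del seed  # deterministic implementation
    n = matrix.n_samples
    if max(k_range) > n - 1:
        raise ValueError(f"max k={max(k_range)} exceeds n-1={n - 1}")
    dist = _distance_matrix(matrix, distance)
    if not np.any(dist > 0):
        warnings.warn("all samples identical: silhouette widths undefined")
        return ClusterScan({k: float("nan") for k in k_range}, None, float("nan"))
    widths: dict[int, float] = {}
    for k in k_range:
        labels = pam(dist, k)
        if len(np.unique(labels)) < 2:
            widths[k] = float("nan")
            continue
        widths[k] = float(silhouette_score(dist, labels, metric="precomputed"))
    finite = {k: w for k, w in widths.items() if not math.isnan(w)}
    if not finite:
        return ClusterScan(widths, None, float("nan"))
    best_k = max(finite, key=finite.get)
    return ClusterScan(widths, best_k, finite[best_k])


def pca_loadings(
    matrix: AbundanceMatrix, n_components: int | None = None, top_m: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Principal components of column-centered abundances.

    Returns (sample scores, per-taxon loadings, top-m |loading| taxa per
    component).  Sign convention: within each component the largest-|loading|
    taxon is made positive, so outputs are reproducible across SVD backends.
    """
    if matrix.n_samples < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = matrix.data.to_numpy(dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("constant matrix has no principal components")
    if n_components is None:
        n_components = min(matrix.n_samples - 1, x.shape[1])
    p = PCA(n_components=n_components)
    scores = p.fit_transform(x)  # PCA centers columns internally
    loadings = p.components_.T  # taxa x components
    pcs = [f"PC{i + 1}" for i in range(n_components)]
    for j in range(n_components):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    scores_df = pd.DataFrame(scores, index=matrix.data.index, columns=pcs)
    load_df = pd.DataFrame(loadings, index=matrix.data.columns, columns=pcs)
    top = {
        pc: load_df[pc].abs().sort_values(ascending=False).head(top_m).index.tolist()
        for pc in pcs
    }
    return scores_df, load_df, top


@dataclass(frozen=True)
class PopulationComparison:
    """Per-taxon two-population comparison results."""

    table: pd.DataFrame
    # columns: median_a, median_b, normalized_a, normalized_b, p_raw,
    #          p_bonferroni, differential
    spearman_rho: float  # correlation of the two populations' median vectors
    spearman_p: float
    n_taxa_tested: int


def compare_populations(
    matrix_a: AbundanceMatrix,
    matrix_b: AbundanceMatrix,
    alpha: float = 0.01,
) -> PopulationComparison:
    """Wilcoxon rank-sum per taxon with Bonferroni control, plus the
    median/max normalized abundances.

    Taxa are the union of both populations' columns (absent = 0).  The
    normalized value for a taxon in a population is its median abundance
    divided by the *maximum* abundance of that taxon observed within the
    population (0 when never observed).  ``differential`` flags taxa with
    Bonferroni-adjusted p < ``alpha``.
    """
    if matrix_a.n_samples < 2 or matrix_b.n_samples < 2:
        raise ValueError("each population needs >= 2 samples")
    taxa = sorted(set(matrix_a.data.columns) | set(matrix_b.data.columns))
    a = matrix_a.data.reindex(columns=taxa, fill_value=0.0)
    b = matrix_b.data.reindex(columns=taxa, fill_value=0.0)
    n_tests = len(taxa)
    rows = []
    for taxon in taxa:
        xa = a[taxon].to_numpy()
        xb = b[taxon].to_numpy()
        if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
            p_raw = 1.0  # constant and identical: no evidence either way
        else:
            method = "exact" if (len(xa) + len(xb)) <= 40 else "asymptotic"
            p_raw = float(
                mannwhitneyu(xa, xb, alternative="two-sided", method=method).pvalue
            )
        p_adj = min(1.0, p_raw * n_tests)
        med_a, med_b = float(np.median(xa)), float(np.median(xb))
        max_a, max_b = float(xa.max()), float(xb.max())
        rows.append(
            {
                "taxon": taxon,
                "median_a": med_a,
                "median_b": med_b,
                "normalized_a": med_a / max_a if max_a > 0 else 0.0,
                "normalized_b": med_b / max_b if max_b > 0 else 0.0,
                "p_raw": p_raw,
                "p_bonferroni": p_adj,
                "differential": p_adj < alpha,
            }
        )
    table = pd.DataFrame(rows).set_index("taxon")
    if n_tests >= 3:
        rho, p = abundance_correlation(
            table["median_a"].to_numpy(), table["median_b"].to_numpy()
        )
    else:
        rho, p = float("nan"), float("nan")  # too few taxa for a rank correlation
    return PopulationComparison(
        table=table, spearman_rho=rho, spearman_p=p, n_taxa_tested=n_tests
    )


def abundance_correlation(
    vector_a: np.ndarray, vector_b: np.ndarray
) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    For n <= 10 the p-value is exact (full enumeration of rank pairings via
    a permutation test); above that, the usual t-approximation.
    """
    vector_a = np.asarray(vector_a, dtype=float)
    vector_b = np.asarray(vector_b, dtype=float)
    if vector_a.shape != vector_b.shape or vector_a.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    n = vector_a.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    res = spearmanr(vector_a, vector_b)
    rho = float(res.statistic)
    if math.isnan(rho):
        return rho, float("nan")
    if n <= 10:
        from itertools import permutations

        from scipy.stats import rankdata

        ra = rankdata(vector_a) - (n + 1) / 2.0
        rb = rankdata(vector_b) - (n + 1) / 2.0
        denom = np.linalg.norm(ra) * np.linalg.norm(rb)
        if denom == 0:
            return rho, float("nan")
        obs = abs(float(ra @ rb))
        perms = np.fromiter(
            (v for p in permutations(rb) for v in p), dtype=float
        ).reshape(-1, n)
        stats = np.abs(perms @ ra)
        p_exact = float(np.mean(stats >= obs - 1e-12))
        return rho, p_exact
    return rho, float(res.pvalue)
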