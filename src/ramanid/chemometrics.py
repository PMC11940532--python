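"""Multivariate exploration of spectra: PCA and hierarchical clustering.

PCA operates on the covariance of column-centered data (no unit-variance
scaling by default) because the spectra entering it are already min-max
scaled to [0, 1]; eigenvalues are then variances on that 0-1 intensity
scale.  Component signs are fixed so each loading's largest-magnitude
entry is positive, making results deterministic.

HCA uses a correlation dissimilarity d_ij = 1 - Pearson(row_i, row_j) and,
by default, a Ward minimum-variance merge implemented as the
Lance-Williams recurrence applied directly to those dissimilarities (the
"Ward.D" convention familiar from R's hclust).  Applying Ward to
non-Euclidean dissimilarities is a pragmatic, widely used choice rather
than a formally proper one; the result records the convention used.
Single/complete/average linkage are delegated to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy as _hier
from scipy.spatial.distance import squareform

from .errors import ConfigError, ValidationError

__all__ = ["PcaResult", "HcaResult", "pca", "hca", "cut_clusters", "cophenetic_matrix"]


@dataclass
class PcaResult:
    """Eigendecomposition outputs of a samples x variables matrix."""

    eigenvalues: np.ndarray          # per-component variance, descending
    explained_pct: np.ndarray        # eigenvalue / total variance * 100
    cumulative_pct: np.ndarray
    scores: np.ndarray               # n_samples x n_components
    loadings: np.ndarray             # n_variables x n_components, orthonormal cols
    mean: np.ndarray
    centered: bool
    scaled: bool


@dataclass
class HcaResult:
    """Agglomerative merge tree in scipy linkage-matrix layout.

    ``merge_tree[i] = (a, b, height, size)`` merges nodes ``a`` and ``b``
    (original samples are 0..n-1; merge ``i`` creates node ``n+i``).
    """

    merge_tree: np.ndarray
    distance_metric: str
    linkage: str
    labels: list[str]


def pca(
    matrix: np.ndarray,
    n_components: int | None = None,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """PCA via SVD of the (optionally centered/scaled) data matrix.

    ``n_components`` defaults to the full rank bound ``min(n-1, p)``; asking
    for more is an error.  Eigenvalues use the n-1 denominator, so their sum
    equals the total column variance of the input.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("PCA needs a 2-D matrix with at least 2 samples")
    n, p = X.shape
    rank_bound = min(n - 1, p)
    if n_components is None:
        n_components = rank_bound
    if not 1 <= n_components <= rank_bound:
        raise ConfigError(
            f"n_components must be in [1, {rank_bound}], got {n_components}"
        )
    mean = X.mean(axis=0) if center else np.zeros(p)
    Xc = X - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValidationError("cannot scale: zero-variance column present")
        Xc = Xc / sd
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    eig = eig[:n_components]
    loadings = Vt[:n_components].T
    scores = U[:, :n_components] * s[:n_components]
    # deterministic sign: largest-magnitude loading entry positive per component
    for j in range(loadings.shape[1]):
        i = np.argmax(np.abs(loadings[:, j]))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total_var = Xc.var(axis=0, ddof=1).sum()
    explained = 100.0 * eig / total_var
    return PcaResult(
        eigenvalues=eig,
        explained_pct=explained,
        cumulative_pct=np.cumsum(explained),
        scores=scores,
        loadings=loadings,
        mean=mean,
        centered=center,
        scaled=scale,
    )


def correlation_dissimilarity(matrix: np.ndarray, labels: list[str] | None = None,
                              half: bool = False) -> np.ndarray:
    """Pairwise d_ij = 1 - Pearson(row_i, row_j) (optionally (1-r)/2)."""
    X = np.asarray(matrix, dtype=float)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        i = int(np.nonzero(sd == 0)[0][0])
        name = labels[i] if labels else f"row {i}"
        raise ValidationError(f"correlation undefined for zero-variance sample {name!r}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return d / 2.0 if half else d


def _ward_lance_williams(d: np.ndarray) -> np.ndarray:
    """Ward.D agglomeration on a square dissimilarity matrix.

    At each step the pair of active clusters at minimal dissimilarity is
    merged (ties: smallest node-id pair); distances to the merged cluster
    follow the Ward Lance-Williams recurrence
        d(k, ij) = [(n_i+n_k) d(k,i) + (n_j+n_k) d(k,j) - n_k d(i,j)] / (n_i+n_j+n_k).
    Returns a scipy-style linkage matrix.
    """
    n = d.shape[0]
    # distances between active nodes, keyed by node id (samples 0..n-1, merges n..2n-2)
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                v = dist[(i, j)]
                if best is None or v < best[0] - 1e-15:
                    best = (v, i, j)
        h, a, b = best
        new = n + step
        Z[step] = (a, b, h, size[a] + size[b])
        size[new] = size[a] + size[b]
        for k in sorted(active):
            if k in (a, b):
                continue
            na, nb, nk = size[a], size[b], size[k]
            dka = dist[(min(a, k), max(a, k))]
            dkb = dist[(min(b, k), max(b, k))]
            dab = dist[(a, b)]
            dist[(k, new)] = ((na + nk) * dka + (nb + nk) * dkb - nk * dab) / (
                na + nb + nk
            )
        active.discard(a)
        active.discard(b)
        active.add(new)
    return Z


def hca(
    matrix: np.ndarray,
    metric: str = "correlation",
    linkage: str = "ward",
    labels: list[str] | None = None,
    half_distance: bool = False,
    ward_squared: bool = False,
) -> HcaResult:
    """Hierarchical clustering of spectra (rows).

    ``metric`` is ``"correlation"`` (1 - Pearson r) or ``"euclidean"``.
    ``linkage`` is ``"ward"`` (Lance-Williams on the raw dissimilarities;
    set ``ward_squared`` to update on squared dissimilarities instead) or
    one of scipy's ``"single"/"complete"/"average"``.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("HCA needs at least 2 samples")
    if labels is None:
        labels = [f"sample{i}" for i in range(X.shape[0])]
    if metric == "correlation":
        d = correlation_dissimilarity(X, labels, half=half_distance)
    elif metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
    else:
        raise ConfigError(f"unknown metric {metric!r}")

    if linkage == "ward":
        if ward_squared:
            Z = _ward_lance_williams(d**2)
            Z[:, 2] = np.sqrt(Z[:, 2])
        else:
            Z = _ward_lance_williams(d)
    elif linkage in ("single", "complete", "average"):
        Z = _hier.linkage(squareform(d, checks=False), method=linkage)
    else:
        raise ConfigError(f"unknown linkage {linkage!r}")
    return HcaResult(merge_tree=Z, distance_metric=metric, linkage=linkage,
                     labels=list(labels))


def cut_clusters(h: HcaResult, k: int) -> np.ndarray:
    """Cluster ids after removing the k-1 highest merges.

    Ids are integers 0..k-1 ordered by each cluster's first-appearing sample.
    """
    n = len(h.labels)
    if not 1 <= k <= n:
        raise ConfigError(f"k must be in [1, {n}], got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):  # apply all but the k-1 highest merges
        a, b = int(h.merge_tree[step, 0]), int(h.merge_tree[step, 1])
        parent[find(a)] = n + step
        parent[find(b)] = n + step
    roots: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i in range(n):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots)
        out[i] = roots[r]
    return out


def cophenetic_matrix(h: HcaResult) -> np.ndarray:
    """Square matrix of cophenetic distances (merge height joining each pair)."""
    from scipy.cluster.hierarchy import cophenet

    return squareform(cophenet(h.merge_tree))
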