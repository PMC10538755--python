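"""Spatial genetic structure: sPCA, Moran's I, and Mantel tests.

Spatial PCA finds axes of the individual allele-frequency matrix that
maximize the product of variance and spatial autocorrelation (Moran's I on a
row-standardized connection network): eigenvalues of
``(1/n) X^T ((W + W^T)/2) X``. Positive eigenvalues capture global structure
(clines, patches), negative ones local structure (neighbour repulsion).
Significance is assessed by Monte-Carlo permutation of individual locations;
Mantel tests correlate genetic and geographic distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform


@dataclass
class ConnectionNetwork:
    coords: np.ndarray  # (n, 2) cell-center coordinates, km
    weights: np.ndarray  # row-standardized, zero diagonal

    @property
    def n(self) -> int:
        return len(self.coords)


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray  # signed, descending
    scores: np.ndarray  # (n, n_axes)
    axis_variance: np.ndarray
    axis_moran: np.ndarray


def jitter_coords(rows, cols, seed=None, width: float = 1.0) -> np.ndarray:
    """Cell centers with a uniform within-cell jitter for co-located points."""
    rng = np.random.default_rng(seed)
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    jit = rng.uniform(-0.5, 0.5, size=(len(rows), 2)) * width
    return np.column_stack([cols + 0.5 + jit[:, 0], rows + 0.5 + jit[:, 1]])


def build_network(coords: np.ndarray, k_neighbors: int = 8) -> ConnectionNetwork:
    """Symmetric k-nearest-neighbour graph, binary, row-standardized.

    Distance ties are broken by index order; k=8 mirrors the Queen's-case
    neighbourhood of the dispersal model.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < k_neighbors + 1:
        raise ValueError("need at least k+1 points")
    d = cdist(coords, coords)
    np.fill_diagonal(d, np.inf)
    # argsort is stable for ties -> index order
    nn = np.argsort(d, axis=1, kind="stable")[:, :k_neighbors]
    A = np.zeros((n, n))
    rows = np.repeat(np.arange(n), k_neighbors)
    A[rows, nn.ravel()] = 1.0
    A = np.maximum(A, A.T)  # symmetrize before row-standardization
    W = A / A.sum(axis=1, keepdims=True)
    return ConnectionNetwork(coords=coords, weights=W)


def morans_I(values: np.ndarray, network: ConnectionNetwork) -> float:
    """Moran's I with row-standardized weights (sum W = n)."""
    x = np.asarray(values, dtype=float)
    if len(x) != network.n:
        raise ValueError("values length must equal node count")
    z = x - x.mean()
    denom = np.sum(z**2)
    if denom == 0:
        raise ValueError("zero-variance input")
    W = network.weights
    return float(len(x) / W.sum() * (z @ W @ z) / denom)


def allele_frequency_matrix(genotypes: np.ndarray) -> np.ndarray:
    """Individuals x alleles matrix of within-individual allele frequencies.

    Each allele at each locus becomes one column with values in
    {0, 0.5, 1}; columns are centered and constant columns dropped.
    """
    g = np.asarray(genotypes)
    n, L, _ = g.shape
    cols = []
    for j in range(L):
        a = g[:, j, :]
        for al in np.unique(a):
            cols.append(((a[:, 0] == al).astype(float) + (a[:, 1] == al)) / 2.0)
    X = np.column_stack(cols)
    X = X - X.mean(axis=0)
    keep = X.std(axis=0) > 0
    return X[:, keep]


def spca(X: np.ndarray, network: ConnectionNetwork) -> SpcaResult:
    """Eigen-decompose ``(1/n) X^T ((W+W^T)/2) X`` on a centered matrix.

    Scores satisfy ``lambda_k = var(scores_k) * I(scores_k)`` exactly.
    Axes with (numerically) zero eigenvalues are dropped.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n != network.n:
        raise ValueError("matrix rows must match network nodes")
    W = network.weights
    H = X.T @ ((W + W.T) / 2.0) @ X / n
    evals, evecs = np.linalg.eigh((H + H.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(1.0, np.abs(evals).max())
    keep = np.abs(evals) > 1e-12 * scale
    evals, evecs = evals[keep], evecs[:, keep]
    scores = X @ evecs
    var = scores.var(axis=0)
    moran = np.array([
        morans_I(scores[:, k], network) if var[k] > 0 else 0.0
        for k in range(scores.shape[1])
    ])
    return SpcaResult(
        eigenvalues=evals, scores=scores, axis_variance=var, axis_moran=moran
    )


def global_local_test(X: np.ndarray, network: ConnectionNetwork,
                      n_perm: int = 999, seed=None):
    """Monte-Carlo test of global/local spatial genetic structure.

    Permutes individual locations (equivalently, rows against the network);
    the statistics are the summed positive (global) and negative-magnitude
    (local) eigenvalue mass. Returns (p_global, p_local) with
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)

    def stats(mat):
        res = spca(mat, network)
        ev = res.eigenvalues
        return ev[ev > 0].sum(), -ev[ev < 0].sum()

    obs_g, obs_l = stats(X)
    count_g = count_l = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(X))
        pg, pl = stats(X[perm])
        count_g += pg >= obs_g
        count_l += pl >= obs_l
    return (1 + count_g) / (1 + n_perm), (1 + count_l) / (1 + n_perm)


def mantel(dist_gen: np.ndarray, dist_geo: np.ndarray, n_perm: int = 999,
           seed=None):
    """Mantel correlation between two distance matrices.

    Pearson r over off-diagonal entries; the permutation p-value shuffles
    row/column order jointly (one-sided, high r extreme).
    """
    A = np.asarray(dist_gen, dtype=float)
    B = np.asarray(dist_geo, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)

    def corr(M1, M2):
        x, y = M1[iu], M2[iu]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(A, B)
    if n_perm < 1:
        return r_obs, np.nan
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(A[np.ix_(perm, perm)], B) >= r_obs:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


def genetic_distances(genotypes: np.ndarray) -> np.ndarray:
    """Euclidean distance between individual allele-frequency vectors."""
    X = allele_frequency_matrix(genotypes)
    return squareform(pdist(X))


def geographic_distances(coords: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(coords, dtype=float)))
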