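"""PCA fitting, out-of-sample projection, and significant-PC selection.

A node's genotype matrix (centred, mean-imputed) is decomposed as
A = U Σ Vᵀ by exact SVD.  The fitted basis keeps the top-k right singular
vectors (SNP loadings), singular values, and the training column means, so
an out-of-sample individual can be imputed and centred with *training*
statistics and projected without refitting.  Training coordinates are
A·V_k = U_k Σ_k, i.e. true PC scores: dominant axes dominate Euclidean
distances, as they do visually in a PC scatter plot.

The number of significant components k is chosen by the classification
task itself: the smallest k maximising leave-one-out five-nearest-neighbour
accuracy on the training data (ties toward smaller k).

Singular-vector signs are normalised (largest-magnitude loading positive);
all downstream quantities — distances and squared loadings — are
sign-invariant anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.spatial.distance

from ._voting import majority_label, neighbor_order

_RANK_RTOL = 1e-10


@dataclass
class PCBasis:
    """Fitted per-node PCA model in SNP space."""

    V: np.ndarray  # (n_snps, k) right singular vectors (SNP loadings)
    sigma: np.ndarray  # (k,) singular values, positive non-increasing
    column_means: np.ndarray  # per-SNP training means for centring/imputation
    snp_ids: np.ndarray

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        self.column_means = np.asarray(self.column_means, dtype=np.float64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=str)
        m, k = self.V.shape
        if self.sigma.shape != (k,):
            raise ValueError("sigma length does not match V columns")
        if self.column_means.shape != (m,) or self.snp_ids.shape != (m,):
            raise ValueError("per-SNP fields do not match V rows")
        if np.any(self.sigma <= 0):
            raise ValueError("singular values must be strictly positive")
        if np.any(np.diff(self.sigma) > 1e-12):
            raise ValueError("singular values must be non-increasing")

    @property
    def k(self) -> int:
        return self.V.shape[1]


@dataclass
class PCCoordinates:
    """Per-sample coordinates in the significant-PC subspace."""

    coords: np.ndarray  # (n_samples, k)
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        if len(self.sample_ids) != self.coords.shape[0]:
            raise ValueError("sample_ids length does not match coordinates")


def _fix_signs(Vt: np.ndarray) -> np.ndarray:
    """Flip each singular vector so its largest-magnitude entry is positive."""
    signs = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return signs


def _svd(X: np.ndarray):
    U, s, Vt = scipy.linalg.svd(X, full_matrices=False, lapack_driver="gesdd")
    flip = _fix_signs(Vt)
    return U * flip[None, :], s, Vt * flip[:, None]


def numerical_rank(sigma: np.ndarray) -> int:
    if len(sigma) == 0 or sigma[0] == 0:
        return 0
    return int((sigma > sigma[0] * _RANK_RTOL).sum())


def fit_pca(
    X: np.ndarray,
    k: int,
    snp_ids,
    column_means,
    sample_ids=None,
) -> tuple[PCBasis, PCCoordinates]:
    """Fit the top-k SVD of a centred matrix.

    ``column_means`` are the training means used by ``center_impute``; they
    travel with the basis for out-of-sample projection.  Raises if ``k``
    exceeds the numerical rank of ``X``.
    """
    X = np.asarray(X, dtype=np.float64)
    U, s, Vt = _svd(X)
    rank = numerical_rank(s)
    if not 1 <= k <= rank:
        raise ValueError(f"k={k} outside [1, rank={rank}]")
    basis = PCBasis(V=Vt[:k].T, sigma=s[:k], column_means=column_means, snp_ids=snp_ids)
    coords = U[:, :k] * s[:k][None, :]
    if sample_ids is None:
        sample_ids = np.arange(X.shape[0]).astype(str)
    return basis, PCCoordinates(coords=coords, sample_ids=sample_ids)


def project(basis: PCBasis, values, missing, snp_ids) -> np.ndarray:
    """Project raw samples into the basis's PC space.

    ``values``/``missing`` may be a single sample (1-D) or a batch (2-D)
    over ``snp_ids``, which must cover every SNP of the basis.  Missing
    entries are imputed with the basis's training column means before
    centring, so an all-missing sample lands exactly at the origin.
    """
    single = np.asarray(values).ndim == 1
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    missing = np.atleast_2d(np.asarray(missing, dtype=bool))
    pos = {s: i for i, s in enumerate(np.asarray(snp_ids, dtype=str))}
    absent = [s for s in basis.snp_ids if s not in pos]
    if absent:
        raise KeyError(f"sample is missing required SNPs: {absent[:10]}")
    idx = np.array([pos[s] for s in basis.snp_ids], dtype=int)
    x = values[:, idx]
    miss = missing[:, idx]
    x = np.where(miss, basis.column_means[None, :], x) - basis.column_means[None, :]
    out = x @ basis.V
    return out[0] if single else out


def loo_knn_accuracy(
    coords: np.ndarray,
    labels: Sequence[str],
    sample_ids=None,
    n_neighbors: int = 5,
) -> float:
    """Leave-one-out k-NN accuracy of majority voting on fixed coordinates.

    Each sample is predicted from its ``n_neighbors`` nearest other samples
    (Euclidean, ties by sample id); no strict majority counts as incorrect.
    """
    coords = np.asarray(coords, dtype=np.float64)
    labels = np.asarray(labels, dtype=str)
    n = coords.shape[0]
    if sample_ids is None:
        sample_ids = np.array([f"{i:06d}" for i in range(n)])
    sample_ids = np.asarray(sample_ids, dtype=str)
    d2 = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(coords)) if n > 1 else np.zeros((n, n))
    correct = 0
    for i in range(n):
        others = np.arange(n) != i
        order = neighbor_order(d2[i, others], sample_ids[others])
        nn = order[: min(n_neighbors, n - 1)]
        pred = majority_label(labels[others][nn])
        if pred is not None and pred == labels[i]:
            correct += 1
    return correct / n if n else float("nan")


def choose_num_pcs(
    X: np.ndarray,
    labels: Sequence[str],
    k_candidates: Sequence[int],
    sample_ids=None,
    n_neighbors: int = 5,
) -> int:
    """The k among the candidates maximising LOO k-NN accuracy.

    The matrix is decomposed once; candidate k values reuse coordinate
    prefixes (PC scores are nested).  Candidates above the numerical rank
    are dropped.  Accuracy ties are broken toward the k with the largest
    relative spectral gap σ_k/σ_{k+1}, then toward smaller k: cutting the
    spectrum inside a near-degenerate block of singular values leaves a
    subspace that rotates arbitrarily when the data change by one sample,
    so among equally accurate choices the stable cut is preferred.
    """
    k_candidates = sorted(set(int(k) for k in k_candidates))
    if not k_candidates:
        raise ValueError("k_candidates is empty")
    labels = np.asarray(labels, dtype=str)
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 breeds to choose the number of PCs")
    X = np.asarray(X, dtype=np.float64)
    U, s, _ = _svd(X)
    rank = numerical_rank(s)
    if rank == 0:
        raise ValueError("degenerate (zero) matrix")
    k_candidates = [k for k in k_candidates if 1 <= k <= rank]
    if not k_candidates:
        raise ValueError(f"no candidate k within matrix rank {rank}")
    kmax = max(k_candidates)
    coords = U[:, :kmax] * s[:kmax][None, :]
    accs = {k: loo_knn_accuracy(coords[:, :k], labels, sample_ids, n_neighbors) for k in k_candidates}
    best_acc = max(accs.values())
    tied = [k for k in k_candidates if accs[k] >= best_acc - 1e-12]

    def gap(k: int) -> float:
        return float(s[k - 1] / s[k]) if k < rank else np.inf

    return int(min(tied, key=lambda k: (-gap(k), k)))
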