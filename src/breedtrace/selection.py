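"""PCA-informative marker ranking and redundancy removal.

Each SNP's PCA score is its leverage on the top-k right singular subspace:
p_j = Σ_i V_k[j, i]², the squared norm of its loading row.  Scores are
non-negative and sum to k.  The highest-scoring SNPs are retained as
candidates, but dense genotyping leaves many of them statistically
redundant (linkage disequilibrium), so a small panel is extracted by
column subset selection: a deterministic column-pivoted QR factorisation
of V_kᵀ over the candidate submatrix picks columns that jointly span the
significant subspace, never spending a pick on a copy of an
already-chosen column while an independent informative column remains.

Panels are nested by construction: the selection order is fixed, and the
three reported tiers P1 ⊂ P2 ⊂ P3 are prefixes of it (default sizes in
ratio 1:2:3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .pca import PCBasis, numerical_rank, _svd


@dataclass
class SnpScoreTable:
    """Per-SNP PCA (leverage) scores for a fitted k-dimensional basis."""

    snp_ids: np.ndarray
    scores: np.ndarray
    k: int

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=str)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.snp_ids.shape != self.scores.shape:
            raise ValueError("snp_ids and scores length mismatch")
        if np.any(self.scores < -1e-12):
            raise ValueError("scores must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        order = np.lexsort((self.snp_ids, -self.scores))
        return pd.DataFrame(
            {"snp_id": self.snp_ids[order], "score": self.scores[order], "rank": np.arange(1, len(order) + 1)}
        )


@dataclass
class SnpPanel:
    """Ordered marker panel with nested tier prefixes P1 ⊂ P2 ⊂ P3."""

    node_name: str
    snp_ids: np.ndarray  # selection order, length = largest tier
    tier_sizes: tuple[int, int, int]
    scores: np.ndarray  # PCA score per selected SNP, aligned with snp_ids

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=str)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("panel selection order contains duplicates")
        t1, t2, t3 = self.tier_sizes
        if not 0 < t1 <= t2 <= t3:
            raise ValueError(f"tier sizes must be positive and ascending, got {self.tier_sizes}")
        if t3 != len(self.snp_ids):
            raise ValueError("largest tier must equal the panel length")
        if self.scores.shape != self.snp_ids.shape:
            raise ValueError("scores length mismatch")

    def tier_ids(self, tier: str) -> np.ndarray:
        sizes = dict(zip(("P1", "P2", "P3"), self.tier_sizes))
        if tier not in sizes:
            raise KeyError(f"unknown tier {tier!r}")
        return self.snp_ids[: sizes[tier]]


def pcaim_scores(basis: PCBasis) -> SnpScoreTable:
    """Leverage score of each SNP on the significant-PC subspace.

    Squared row norms of V_k; invariant to sample permutation and to sign
    flips of singular vectors, and total mass equals k exactly.
    """
    scores = np.einsum("jk,jk->j", basis.V, basis.V)
    return SnpScoreTable(snp_ids=basis.snp_ids, scores=scores, k=basis.k)


def top_candidates(scores: SnpScoreTable, n_top: int) -> np.ndarray:
    """The ``n_top`` highest-scoring SNP ids, ties broken by id."""
    if n_top > len(scores.snp_ids):
        raise ValueError(f"n_top={n_top} exceeds {len(scores.snp_ids)} scored SNPs")
    order = np.lexsort((scores.snp_ids, -scores.scores))
    return scores.snp_ids[order[:n_top]]


def cssp_select(X_cand: np.ndarray, snp_ids, k: int, c: int) -> np.ndarray:
    """Greedy column subset selection over candidate SNP columns.

    Decomposes the (centred) candidate submatrix, then orders columns by
    column-pivoted QR of the k × n matrix V_kᵀ.  The pivot order is
    deterministic, so truncations at different ``c`` are nested prefixes.
    QR pivoting ranks min(k, c) columns by residual norm; when ``c``
    exceeds k the remaining positions are filled in descending leverage
    order (ties by SNP id), which keeps the ordering deterministic and
    informative beyond the spanning set.
    """
    snp_ids = np.asarray(snp_ids, dtype=str)
    X_cand = np.asarray(X_cand, dtype=np.float64)
    n_cand = X_cand.shape[1]
    if snp_ids.shape != (n_cand,):
        raise ValueError("snp_ids length does not match candidate columns")
    if not 1 <= c <= n_cand:
        raise ValueError(f"c={c} outside [1, {n_cand}]")
    _, s, Vt = _svd(X_cand)
    rank = numerical_rank(s)
    if rank == 0:
        raise ValueError("degenerate candidate matrix (all columns zero)")
    if k > rank:
        raise ValueError(f"k={k} exceeds candidate-matrix rank {rank}")
    Vk_t = Vt[:k]  # k x n_cand
    _, _, piv = scipy.linalg.qr(Vk_t, pivoting=True, mode="economic")
    head = list(piv[: min(k, n_cand)])
    if c > len(head):
        lev = np.einsum("ij,ij->j", Vk_t, Vk_t)
        rest = np.setdiff1d(np.arange(n_cand), head, assume_unique=False)
        rest = rest[np.lexsort((snp_ids[rest], -lev[rest]))]
        head.extend(rest.tolist())
    return snp_ids[np.array(head[:c], dtype=int)]


def build_panels(
    X: np.ndarray,
    snp_ids,
    basis: PCBasis,
    n_top: int,
    p1_size: int,
    node_name: str = "",
    tier_sizes: tuple[int, int, int] | None = None,
) -> SnpPanel:
    """Rank, retain top candidates, remove redundancy, cut nested tiers.

    ``X`` is the node's centred matrix over ``snp_ids`` (the basis's SNP
    order).  Default tiers are (p1, 2·p1, 3·p1); an explicit
    ``tier_sizes`` (e.g. 10/25/50) overrides the 1:2:3 ratio while keeping
    prefix nesting.
    """
    snp_ids = np.asarray(snp_ids, dtype=str)
    if not np.array_equal(snp_ids, basis.snp_ids):
        raise ValueError("basis SNP order does not match the supplied matrix")
    if tier_sizes is None:
        tier_sizes = (p1_size, 2 * p1_size, 3 * p1_size)
    c = tier_sizes[2]
    if c > n_top:
        raise ValueError(f"largest tier {c} exceeds candidate count n_top={n_top}")
    scores = pcaim_scores(basis)
    cand_ids = top_candidates(scores, n_top)
    pos = {s: i for i, s in enumerate(snp_ids)}
    cand_idx = np.array([pos[s] for s in cand_ids], dtype=int)
    order = cssp_select(X[:, cand_idx], cand_ids, basis.k, c)
    score_of = dict(zip(scores.snp_ids, scores.scores))
    return SnpPanel(
        node_name=node_name,
        snp_ids=order,
        tier_sizes=tier_sizes,
        scores=np.array([score_of[s] for s in order]),
    )
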