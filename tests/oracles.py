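"""Independent reference implementations used only to check the package.

These are deliberately written from first principles (textbook formulas,
brute-force enumeration, dense numpy linear algebra) and share no code
with the implementation they validate.
"""

from __future__ import annotations

import itertools

import numpy as np


def weir_cockerham_fst(counts: np.ndarray, missing: np.ndarray, pops) -> float:
    """Multi-SNP Weir–Cockerham theta (ratio of averages over SNPs).

    ``counts`` holds per-individual allele counts (0/1/2) of an arbitrary
    but consistent allele per SNP; ``pops`` labels rows.  Uses the
    standard two-level variance components a (between populations),
    b (between individuals within populations), c (within individuals).
    """
    pops = np.asarray(pops)
    groups = sorted(set(pops.tolist()))
    a_sum = bc_sum = 0.0
    for j in range(counts.shape[1]):
        n_i, p_i, h_i = [], [], []
        for g in groups:
            rows = (pops == g) & ~missing[:, j]
            n = int(rows.sum())
            if n == 0:
                continue
            vals = counts[rows, j]
            n_i.append(n)
            p_i.append(vals.sum() / (2.0 * n))
            h_i.append((vals == 1).mean())
        r = len(n_i)
        if r < 2:
            continue
        n_i = np.array(n_i, dtype=float)
        p_i = np.array(p_i)
        h_i = np.array(h_i)
        nbar = n_i.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        a_sum += a
        bc_sum += a + b + c
    return a_sum / bc_sum if bc_sum else float("nan")


def leverage_by_regression(X: np.ndarray, k: int) -> np.ndarray:
    """Per-column leverage on the top-k PC subspace via least squares.

    Regresses each centred column on the top-k PC coordinate matrix
    (numpy SVD); the squared norm of the coefficient vector equals the
    column's squared loading row norm.
    """
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = U[:, :k] * s[:k]
    beta, *_ = np.linalg.lstsq(coords, X, rcond=None)
    return (beta**2).sum(axis=0)


def reconstruction_error(X: np.ndarray, cols) -> float:
    """Squared Frobenius error of projecting X onto the span of its columns."""
    S = X[:, list(cols)]
    Q, _ = np.linalg.qr(S)
    return float(np.linalg.norm(X - Q @ (Q.T @ X)) ** 2)


def best_subset_error(X: np.ndarray, c: int) -> float:
    """Exhaustive-optimal c-column subset reconstruction error."""
    n = X.shape[1]
    return min(reconstruction_error(X, S) for S in itertools.combinations(range(n), c))
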