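"""Genotype encoding and quality control.

Raw diploid allele calls are converted into the numeric matrix analysed by
PCA: per-SNP minor-allele counts in {0, 1, 2} with an explicit missingness
mask.  QC applies a strict missing-fraction filter (a SNP is removed when
its missing fraction strictly exceeds the threshold) and drops monomorphic
columns, which carry zero variance and therefore zero PCA signal.  Missing
entries are mean-imputed and columns centred; the column means are retained
so that out-of-sample individuals can be projected with the training means.

The 0/1/2 minor-allele-count encoding is equivalent, up to a per-column
affine transform absorbed by centring, to any other linear diploid coding,
so principal components and leverage scores do not depend on this choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import RawGenotypeTable

MISSING_ALLELE = "0"


class EncodingError(ValueError):
    """Raised for genotype data that cannot be encoded (e.g. >2 alleles)."""


@dataclass
class GenotypeMatrix:
    """Encoded sample-by-SNP genotype table with missingness mask and labels.

    Attributes
    ----------
    values : (n_samples, n_snps) int8
        Minor-allele counts; entries under ``missing`` are 0 placeholders.
    missing : (n_samples, n_snps) bool
        True where the call is missing.
    sample_ids, snp_ids : arrays of str
    labels : pandas.Series
        Breed per sample, indexed by sample id in row order.
    minor_allele, major_allele : arrays of str
        Allele characters per SNP ("-" when undefined, e.g. monomorphic).
    """

    values: np.ndarray
    missing: np.ndarray
    sample_ids: np.ndarray
    snp_ids: np.ndarray
    labels: pd.Series
    minor_allele: np.ndarray
    major_allele: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.snp_ids = np.asarray(self.snp_ids, dtype=str)
        n, m = self.values.shape
        if self.missing.shape != (n, m):
            raise ValueError("missing mask shape does not match values")
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError("id arrays do not match matrix shape")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        if not self.labels.index.equals(pd.Index(self.sample_ids)):
            self.labels = self.labels.reindex(self.sample_ids)
            if self.labels.isna().any():
                missing = self.labels.index[self.labels.isna()].tolist()
                raise ValueError(f"samples without breed label: {missing}")
        # placeholder convention: masked entries hold 0
        self.values = np.where(self.missing, 0, self.values).astype(np.int8)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    @property
    def breeds(self) -> list[str]:
        return sorted(set(self.labels))

    def missing_fraction(self) -> np.ndarray:
        """Per-SNP fraction of missing calls."""
        if self.n_samples == 0:
            return np.zeros(self.n_snps)
        return self.missing.mean(axis=0)

    def maf(self) -> np.ndarray:
        """Per-SNP minor-allele frequency among non-missing calls (NaN if none)."""
        called = (~self.missing).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(self.missing, 0, self.values).sum(axis=0) / (2.0 * called)
        return np.where(called > 0, freq, np.nan)

    def restrict_samples(self, selector) -> "GenotypeMatrix":
        """Subset rows by boolean mask, index array, or list of sample ids."""
        idx = _as_row_index(selector, self.sample_ids)
        return GenotypeMatrix(
            values=self.values[idx],
            missing=self.missing[idx],
            sample_ids=self.sample_ids[idx],
            snp_ids=self.snp_ids,
            labels=self.labels.iloc[idx],
            minor_allele=self.minor_allele,
            major_allele=self.major_allele,
        )

    def restrict_snps(self, selector) -> "GenotypeMatrix":
        """Subset columns by boolean mask, index array, or list of SNP ids."""
        idx = _as_row_index(selector, self.snp_ids)
        return GenotypeMatrix(
            values=self.values[:, idx],
            missing=self.missing[:, idx],
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[idx],
            labels=self.labels,
            minor_allele=np.asarray(self.minor_allele)[idx],
            major_allele=np.asarray(self.major_allele)[idx],
        )


def _as_row_index(selector, ids: np.ndarray) -> np.ndarray:
    selector = np.asarray(selector)
    if selector.dtype == bool:
        if len(selector) != len(ids):
            raise ValueError("boolean selector length mismatch")
        return np.flatnonzero(selector)
    if selector.dtype.kind in "iu":
        return selector
    pos = {s: i for i, s in enumerate(ids)}
    try:
        return np.array([pos[s] for s in selector], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown id {exc.args[0]!r}") from None


def matrix_from_counts(
    counts: np.ndarray,
    missing: np.ndarray,
    sample_ids,
    snp_ids,
    labels: pd.Series,
    allele_a,
    allele_b,
) -> GenotypeMatrix:
    """Build a GenotypeMatrix from counts of allele ``b``.

    Columns where allele ``b`` is the more frequent among non-missing calls
    are flipped to minor-allele counts (ties resolved toward the
    lexicographically smaller allele character, which is then "minor").
    """
    counts = np.asarray(counts, dtype=np.int8)
    missing = np.asarray(missing, dtype=bool)
    allele_a = np.asarray(allele_a, dtype=str)
    allele_b = np.asarray(allele_b, dtype=str)
    called = (~missing).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_b = np.where(missing, 0, counts).sum(axis=0) / (2.0 * called)
    freq_b = np.where(called > 0, freq_b, np.nan)
    with np.errstate(invalid="ignore"):
        flip = (freq_b > 0.5) | ((freq_b == 0.5) & (allele_a < allele_b))
    flip = np.where(np.isnan(freq_b), False, flip)
    values = np.where(flip[None, :], 2 - counts, counts).astype(np.int8)
    values[missing] = 0
    minor = np.where(flip, allele_a, allele_b)
    major = np.where(flip, allele_b, allele_a)
    return GenotypeMatrix(values, missing, sample_ids, snp_ids, labels, minor, major)


def encode(raw: RawGenotypeTable, labels: pd.Series) -> GenotypeMatrix:
    """Encode raw allele-character calls as minor-allele counts.

    Per SNP the minor allele is the less frequent allele among non-missing
    calls (tie: lexicographically smaller character).  SNPs with more than
    two distinct alleles raise :class:`EncodingError`.  Monomorphic or
    fully missing SNPs are retained here with zero counts and flagged
    implicitly (minor allele "-"); they are removed by
    :func:`filter_missing`.
    """
    n, m = len(raw.sample_ids), len(raw.snp_ids)
    values = np.zeros((n, m), dtype=np.int8)
    missing = np.zeros((n, m), dtype=bool)
    minor = np.empty(m, dtype="<U8")
    major = np.empty(m, dtype="<U8")
    for j in range(m):
        a1 = raw.a1[:, j]
        a2 = raw.a2[:, j]
        miss = (a1 == MISSING_ALLELE) | (a2 == MISSING_ALLELE)
        missing[:, j] = miss
        called1, called2 = a1[~miss], a2[~miss]
        alleles, cnts = np.unique(np.concatenate([called1, called2]), return_counts=True)
        if len(alleles) > 2:
            raise EncodingError(
                f"SNP {raw.snp_ids[j]!r} has {len(alleles)} alleles: {alleles.tolist()}"
            )
        if len(alleles) == 0:
            minor[j], major[j] = "-", "-"
            continue
        if len(alleles) == 1:
            minor[j], major[j] = "-", alleles[0]
            continue
        if cnts[0] < cnts[1] or (cnts[0] == cnts[1] and alleles[0] < alleles[1]):
            mn, mj = alleles[0], alleles[1]
        else:
            mn, mj = alleles[1], alleles[0]
        minor[j], major[j] = mn, mj
        values[~miss, j] = (called1 == mn).astype(np.int8) + (called2 == mn).astype(np.int8)
    return GenotypeMatrix(values, missing, raw.sample_ids, raw.snp_ids, labels, minor, major)


def filter_missing(gm: GenotypeMatrix, max_missing_fraction: float = 0.10) -> GenotypeMatrix:
    """Drop SNPs missing in strictly more than ``max_missing_fraction`` of samples.

    A SNP missing in exactly the threshold fraction is retained.  Columns
    monomorphic among non-missing calls (including all-missing columns) are
    dropped as well: they have zero variance and break centring-based
    scaling downstream.  The sample set is unchanged; the filter is
    idempotent.
    """
    if not 0 <= max_missing_fraction < 1:
        raise ValueError("max_missing_fraction must be in [0, 1)")
    frac = gm.missing_fraction()
    vals = np.ma.masked_array(gm.values, mask=gm.missing)
    called = (~gm.missing).sum(axis=0)
    poly = np.zeros(gm.n_snps, dtype=bool)
    has_calls = called > 0
    if gm.n_snps:
        vmax = vals.max(axis=0).filled(0)
        vmin = vals.min(axis=0).filled(0)
        poly = has_calls & (vmax > vmin)
    keep = (frac <= max_missing_fraction) & poly
    return gm.restrict_snps(keep)


def center_impute(gm: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing entries and centre every column to mean zero.

    Returns the centred float matrix and the per-column means of the
    non-missing entries (needed to project out-of-sample individuals).
    Raises if any column is all-missing or monomorphic; running
    :func:`filter_missing` first guarantees the precondition.
    """
    called = (~gm.missing).sum(axis=0)
    if np.any(called == 0):
        bad = gm.snp_ids[called == 0].tolist()
        raise ValueError(f"all-missing SNP columns: {bad[:5]}")
    vals = np.ma.masked_array(gm.values, mask=gm.missing)
    if gm.n_snps and np.any(vals.max(axis=0) == vals.min(axis=0)):
        flat = np.asarray(vals.max(axis=0) == vals.min(axis=0))
        raise ValueError(f"monomorphic SNP columns: {gm.snp_ids[flat][:5].tolist()}")
    means = np.where(gm.missing, 0, gm.values).sum(axis=0) / called
    X = np.where(gm.missing, means[None, :], gm.values).astype(np.float64)
    X -= means[None, :]
    return X, means
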