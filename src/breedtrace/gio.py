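"""Text-file input/output: PED/MAP genotypes, label tables, marker panels.

The on-disk genotype dialect is PLINK-style text PED/MAP.  A PED row holds
family id, sample id, four placeholder columns, then two allele characters
per SNP with "0" as the missing code.  Readers reject malformed input with
line numbers rather than silently repairing it; every writer/reader pair is
an inverse on valid data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .selection import SnpPanel

MISSING_ALLELE = "0"
_TIER_TOKENS = ("P1", "P2", "P3")


class ParseError(ValueError):
    """Malformed input file; the message carries the file and line number."""


@dataclass
class RawGenotypeTable:
    """Unencoded allele-character calls for a rectangular sample-by-SNP table."""

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    a1: np.ndarray  # (n_samples, n_snps) first allele character, "0" = missing
    a2: np.ndarray  # (n_samples, n_snps) second allele character
    family_ids: np.ndarray | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=str)
        self.snp_ids = np.asarray(self.snp_ids, dtype=str)
        n, m = len(self.sample_ids), len(self.snp_ids)
        if self.a1.shape != (n, m) or self.a2.shape != (n, m):
            raise ValueError("allele arrays do not match id dimensions")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")


def read_genotypes(ped_path, map_path) -> RawGenotypeTable:
    """Parse a PED/MAP pair, preserving file order.

    A call with either allele "0" is treated as missing (both alleles set
    to "0").  Ragged rows, duplicate ids, and PED/MAP length mismatches
    raise :class:`ParseError` naming the offending line.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    snp_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{map_path.name} line {lineno}: expected 4 fields, got {len(fields)}")
            chrom.append(fields[0])
            snp_ids.append(fields[1])
            try:
                pos.append(int(fields[3]))
            except ValueError:
                raise ParseError(f"{map_path.name} line {lineno}: non-integer position {fields[3]!r}") from None
    if len(set(snp_ids)) != len(snp_ids):
        dup = pd.Series(snp_ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise ParseError(f"{map_path.name}: duplicate SNP id {dup!r}")
    m = len(snp_ids)

    fam_ids: list[str] = []
    sample_ids: list[str] = []
    rows1: list[np.ndarray] = []
    rows2: list[np.ndarray] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * m:
                raise ParseError(
                    f"{ped_path.name} line {lineno}: expected {6 + 2 * m} fields "
                    f"(6 + 2 x {m} SNPs), got {len(fields)}"
                )
            fam_ids.append(fields[0])
            sample_ids.append(fields[1])
            alleles = np.array(fields[6:], dtype="<U8")
            a1 = alleles[0::2].copy()
            a2 = alleles[1::2].copy()
            miss = (a1 == MISSING_ALLELE) | (a2 == MISSING_ALLELE)
            a1[miss] = MISSING_ALLELE
            a2[miss] = MISSING_ALLELE
            rows1.append(a1)
            rows2.append(a2)
    if len(set(sample_ids)) != len(sample_ids):
        dup = pd.Series(sample_ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise ParseError(f"{ped_path.name}: duplicate sample id {dup!r}")
    n = len(sample_ids)
    shape = (n, m)
    a1_arr = np.vstack(rows1) if rows1 else np.empty(shape, dtype="<U8")
    a2_arr = np.vstack(rows2) if rows2 else np.empty(shape, dtype="<U8")
    return RawGenotypeTable(
        sample_ids=np.array(sample_ids, dtype=str),
        snp_ids=np.array(snp_ids, dtype=str),
        a1=a1_arr.reshape(shape),
        a2=a2_arr.reshape(shape),
        family_ids=np.array(fam_ids, dtype=str),
        chrom=np.array(chrom, dtype=str),
        pos=np.array(pos, dtype=int),
    )


# allele pairs cycled per SNP when writing; first char is lexicographically
# smaller so that re-encoding after a frequency tie is stable
_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"))


def write_ped_map(gm, ped_path, map_path) -> None:
    """Write an encoded genotype matrix as a PED/MAP pair.

    The minor allele is written as the lexicographically smaller character
    of a per-SNP pair, so ``encode(read_genotypes(...))`` reproduces the
    matrix and mask exactly (allele letters are canonicalised, counts are
    not).  Family id column carries the breed label.
    """
    with open(map_path, "w") as fh:
        for j, snp in enumerate(gm.snp_ids):
            fh.write(f"{j % 29 + 1}\t{snp}\t0\t{j + 1}\n")
    pair_idx = np.arange(gm.n_snps) % len(_ALLELE_PAIRS)
    minor = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    major = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(gm.sample_ids):
            fields = [str(gm.labels.iloc[i]), str(sample), "0", "0", "0", "-9"]
            v = gm.values[i]
            miss = gm.missing[i]
            for j in range(gm.n_snps):
                if miss[j]:
                    fields.append("0 0")
                elif v[j] == 0:
                    fields.append(f"{major[j]} {major[j]}")
                elif v[j] == 1:
                    fields.append(f"{minor[j]} {major[j]}")
                else:
                    fields.append(f"{minor[j]} {minor[j]}")
            fh.write(" ".join(fields) + "\n")


def read_labels(path, samples) -> pd.Series:
    """Read a sample→breed TSV (header ``sample_id<TAB>breed``).

    Every requested sample must appear exactly once; a missing or
    duplicated sample raises with its id.
    """
    path = Path(path)
    seen: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline()
        if header.split("\t")[:2] != ["sample_id", "breed"] and header.split()[:2] != ["sample_id", "breed"]:
            raise ParseError(f"{path.name} line 1: expected header 'sample_id\\tbreed'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path.name} line {lineno}: expected 2 tab-separated fields")
            sample, breed = fields
            if sample in seen:
                raise ParseError(f"{path.name} line {lineno}: duplicate sample {sample!r}")
            seen[sample] = breed
    samples = list(samples)
    absent = [s for s in samples if s not in seen]
    if absent:
        raise ParseError(f"{path.name}: no label for sample {absent[0]!r}")
    return pd.Series([seen[s] for s in samples], index=pd.Index(samples, name="sample_id"), name="breed")


def write_labels(labels: pd.Series, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tbreed\n")
        for sample, breed in labels.items():
            fh.write(f"{sample}\t{breed}\n")


def write_panel(panel: "SnpPanel", path) -> None:
    """Write a marker panel as TSV (rank, snp_id, pcaim_score, node_name, tier)."""
    if len(panel.snp_ids) == 0:
        raise ValueError("refusing to write an empty panel")
    t1, t2, _ = panel.tier_sizes
    with open(path, "w") as fh:
        fh.write("rank\tsnp_id\tpcaim_score\tnode_name\ttier\n")
        for i, (snp, score) in enumerate(zip(panel.snp_ids, panel.scores)):
            tier = "P1" if i < t1 else ("P2" if i < t2 else "P3")
            fh.write(f"{i + 1}\t{snp}\t{float(score)!r}\t{panel.node_name}\t{tier}\n")


def read_panel(path) -> "SnpPanel":
    """Inverse of :func:`write_panel`."""
    from .selection import SnpPanel

    path = Path(path)
    ranks: list[int] = []
    snps: list[str] = []
    scores: list[float] = []
    nodes: list[str] = []
    tiers: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["rank", "snp_id", "pcaim_score", "node_name", "tier"]:
            raise ParseError(f"{path.name} line 1: unexpected header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ParseError(f"{path.name} line {lineno}: expected 5 fields")
            rank, snp, score, node, tier = fields
            if tier not in _TIER_TOKENS:
                raise ParseError(f"{path.name} line {lineno}: unknown tier token {tier!r}")
            ranks.append(int(rank))
            snps.append(snp)
            scores.append(float(score))
            nodes.append(node)
            tiers.append(tier)
    if ranks != list(range(1, len(ranks) + 1)):
        raise ParseError(f"{path.name}: ranks are not consecutive from 1")
    if len(set(nodes)) != 1:
        raise ParseError(f"{path.name}: mixed node names {sorted(set(nodes))}")
    n1 = tiers.count("P1")
    n2 = tiers.count("P2")
    tier_sizes = (n1, n1 + n2, len(tiers))
    return SnpPanel(
        node_name=nodes[0],
        snp_ids=np.array(snps, dtype=str),
        tier_sizes=tier_sizes,
        scores=np.array(scores, dtype=float),
    )
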