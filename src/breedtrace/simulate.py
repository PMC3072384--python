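"""Multi-breed diploid SNP genotype simulator with a planted hierarchy.

Allele-frequency drift follows the Balding-Nichols model: along each branch
of the breed tree with differentiation parameter F ∈ (0, 1), the child
frequency is drawn Beta(p(1−F)/F, (1−p)(1−F)/F) around the parent
frequency p, so the expected between-population variance of the frequency
is F·p(1−p) and multi-SNP F_ST estimates recover F.  Frequencies are
clamped to [0.01, 0.99] after each draw to avoid fixation.

Genotypes are Binomial(2, p_breed) per individual and SNP.  Linkage
disequilibrium is emulated by noisy duplication: a fraction of base SNPs
is copied (redundancy_factor − 1 extra columns each), with each duplicated
entry independently resampled from the breed frequency at a small
corruption probability — reproducing the redundant-marker failure mode
that column subset selection is meant to remove, without coalescent
machinery.  Missing calls are MCAR at a fixed per-entry rate.

Identical seeds give bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import gio
from .encoding import GenotypeMatrix, matrix_from_counts

_FREQ_CLAMP = (0.01, 0.99)


class SpecError(ValueError):
    """Invalid simulation specification; the message names the field."""


@dataclass(frozen=True)
class BreedTreeSpec:
    """Specification of a hierarchical multi-breed genotype dataset.

    ``nodes`` is a nested mapping of group names to subtrees; a list value
    (or ``None``) marks leaf breeds.  ``branch_fst`` is either one F for
    every branch or a mapping from node/breed name to the F of the branch
    entering it.
    """

    nodes: Mapping
    branch_fst: float | Mapping[str, float]
    n_per_breed: int = 40
    n_snps: int = 2000
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    missing_rate: float = 0.05
    redundancy_factor: int = 1
    redundancy_fraction: float = 0.2
    redundancy_flip_prob: float = 0.05
    seed: int = 0


@dataclass
class TruthRecord:
    """Ground truth backing a simulated dataset."""

    ancestral_freq: pd.Series  # per SNP (duplicates share the base value)
    breed_freq: pd.DataFrame  # SNP x breed drifted frequencies
    dup_group: pd.Series  # per SNP duplicate-group id (= base SNP id)
    labels: pd.Series  # sample -> breed


def _normalize(nodes) -> dict:
    """Canonicalise the nested grouping to name -> (dict | None)."""
    if isinstance(nodes, Mapping):
        out = {}
        for name, sub in nodes.items():
            if sub is None:
                out[str(name)] = None
            elif isinstance(sub, Mapping):
                out[str(name)] = _normalize(sub)
            elif isinstance(sub, (list, tuple)):
                out[str(name)] = {str(b): None for b in sub}
            else:
                raise SpecError(f"nodes: cannot interpret subtree under {name!r}")
        return out
    raise SpecError("nodes: expected a mapping of group names to subtrees")


def _leaves(tree: dict) -> list[str]:
    out: list[str] = []
    for name, sub in tree.items():
        if sub is None:
            out.append(name)
        else:
            out.extend(_leaves(sub))
    return out


def _all_names(tree: dict) -> list[str]:
    out: list[str] = []
    for name, sub in tree.items():
        out.append(name)
        if sub is not None:
            out.extend(_all_names(sub))
    return out


def validate_spec(spec: BreedTreeSpec) -> dict:
    """Check every field; return the canonicalised breed tree."""
    tree = _normalize(spec.nodes)
    breeds = _leaves(tree)
    if len(breeds) == 0:
        raise SpecError("nodes: no leaf breeds")
    if len(set(_all_names(tree))) != len(_all_names(tree)):
        raise SpecError("nodes: breed/group names must be unique across the tree")
    fst = spec.branch_fst
    if isinstance(fst, Mapping):
        missing = [n for n in _all_names(tree) if n not in fst]
        if missing:
            raise SpecError(f"branch_fst: no value for branch into {missing[0]!r}")
        values = [fst[n] for n in _all_names(tree)]
    else:
        values = [fst]
    if any(not (0 < f < 1) for f in values):
        raise SpecError("branch_fst: every F must lie in (0, 1)")
    if spec.n_per_breed < 1:
        raise SpecError("n_per_breed: must be a positive integer")
    if spec.n_snps < 0:
        raise SpecError("n_snps: must be non-negative")
    lo, hi = spec.ancestral_freq_range
    if not (0 < lo < hi < 1):
        raise SpecError("ancestral_freq_range: need 0 < lo < hi < 1")
    if not (0 <= spec.missing_rate < 1):
        raise SpecError("missing_rate: must be in [0, 1)")
    if spec.redundancy_factor < 1:
        raise SpecError("redundancy_factor: must be an integer >= 1")
    if not (0 <= spec.redundancy_fraction <= 1):
        raise SpecError("redundancy_fraction: must be in [0, 1]")
    if not (0 <= spec.redundancy_flip_prob < 0.5):
        raise SpecError("redundancy_flip_prob: must be in [0, 0.5)")
    return tree


def _branch_fst(spec: BreedTreeSpec, name: str) -> float:
    if isinstance(spec.branch_fst, Mapping):
        return float(spec.branch_fst[name])
    return float(spec.branch_fst)


def _drift(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return np.clip(rng.beta(a, b), *_FREQ_CLAMP)


def simulate_dataset(spec: BreedTreeSpec) -> tuple[GenotypeMatrix, TruthRecord]:
    """Draw a dataset under the spec; deterministic given the seed."""
    tree = validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    p_anc = rng.uniform(*spec.ancestral_freq_range, size=spec.n_snps)

    breed_freq: dict[str, np.ndarray] = {}

    def descend(subtree: dict, p_parent: np.ndarray) -> None:
        for name, sub in subtree.items():
            p_child = _drift(rng, p_parent, _branch_fst(spec, name))
            if sub is None:
                breed_freq[name] = p_child
            else:
                descend(sub, p_child)

    descend(tree, p_anc)
    breeds = _leaves(tree)

    sample_ids = []
    labels = []
    blocks = []
    for breed in breeds:
        p = breed_freq[breed]
        blocks.append(rng.binomial(2, p, size=(spec.n_per_breed, spec.n_snps)))
        sample_ids.extend(f"{breed}_{i:03d}" for i in range(spec.n_per_breed))
        labels.extend([breed] * spec.n_per_breed)
    counts = np.vstack(blocks) if blocks else np.zeros((0, spec.n_snps), dtype=int)
    n_total = counts.shape[0]

    base_ids = [f"snp{j:05d}" for j in range(spec.n_snps)]
    snp_ids = list(base_ids)
    dup_group = {s: s for s in base_ids}
    freq_by_snp = {s: np.array([breed_freq[b][j] for b in breeds]) for j, s in enumerate(base_ids)}
    anc_by_snp = {s: p_anc[j] for j, s in enumerate(base_ids)}

    if spec.redundancy_factor > 1 and spec.n_snps > 0:
        n_dup = int(round(spec.redundancy_fraction * spec.n_snps))
        dup_base = np.sort(rng.choice(spec.n_snps, size=n_dup, replace=False))
        breed_of_row = np.repeat(np.arange(len(breeds)), spec.n_per_breed)
        extra_cols = []
        for j in dup_base:
            p_row = np.array([breed_freq[b][j] for b in breeds])[breed_of_row]
            for rep in range(1, spec.redundancy_factor):
                col = counts[:, j].copy()
                flip = rng.random(n_total) < spec.redundancy_flip_prob
                if flip.any():
                    col[flip] = rng.binomial(2, p_row[flip])
                extra_cols.append(col)
                dup_id = f"{base_ids[j]}_r{rep}"
                snp_ids.append(dup_id)
                dup_group[dup_id] = base_ids[j]
                freq_by_snp[dup_id] = np.array([breed_freq[b][j] for b in breeds])
                anc_by_snp[dup_id] = p_anc[j]
        if extra_cols:
            counts = np.hstack([counts, np.column_stack(extra_cols)])

    missing = rng.random(counts.shape) < spec.missing_rate
    labels = pd.Series(labels, index=pd.Index(sample_ids, name="sample_id"), name="breed")

    m = len(snp_ids)
    pair_idx = np.arange(m) % len(gio._ALLELE_PAIRS)
    allele_a = np.array([gio._ALLELE_PAIRS[i][0] for i in pair_idx])
    allele_b = np.array([gio._ALLELE_PAIRS[i][1] for i in pair_idx])
    gm = matrix_from_counts(counts, missing, sample_ids, snp_ids, labels, allele_a, allele_b)

    truth = TruthRecord(
        ancestral_freq=pd.Series({s: anc_by_snp[s] for s in snp_ids}, name="ancestral_freq"),
        breed_freq=pd.DataFrame(
            np.vstack([freq_by_snp[s] for s in snp_ids]) if m else np.zeros((0, len(breeds))),
            index=pd.Index(snp_ids, name="snp_id"),
            columns=breeds,
        ),
        dup_group=pd.Series({s: dup_group[s] for s in snp_ids}, name="dup_group"),
        labels=labels,
    )
    return gm, truth


def two_level_spec(
    n_groups: int = 2,
    breeds_per_group: int = 3,
    between_fst: float = 0.15,
    within_fst: float = 0.05,
    n_per_breed: int = 40,
    n_snps: int = 2000,
    missing_rate: float = 0.05,
    redundancy_factor: int = 3,
    redundancy_fraction: float = 0.2,
    redundancy_flip_prob: float = 0.05,
    seed: int = 0,
) -> BreedTreeSpec:
    """Convenience spec: groups of breeds with between/within differentiation.

    Defaults describe the standard end-to-end study condition: six breeds
    in two groups (between-group F_ST 0.15, within-group 0.05), 40
    individuals per breed, 2,000 base SNPs, 5% missing calls, and one
    fifth of the SNPs duplicated twice with 5% per-entry corruption.
    """
    nodes = {}
    fst: dict[str, float] = {}
    for g in range(n_groups):
        gname = f"group{g + 1}"
        members = [f"breed{g + 1}{chr(ord('a') + i)}" for i in range(breeds_per_group)]
        nodes[gname] = members
        fst[gname] = between_fst
        for b in members:
            fst[b] = within_fst
    return BreedTreeSpec(
        nodes=nodes,
        branch_fst=fst,
        n_per_breed=n_per_breed,
        n_snps=n_snps,
        missing_rate=missing_rate,
        redundancy_factor=redundancy_factor,
        redundancy_fraction=redundancy_fraction,
        redundancy_flip_prob=redundancy_flip_prob,
        seed=seed,
    )


def hudson_fst(gm: GenotypeMatrix) -> float:
    """Multi-SNP Hudson-style F_ST over all breed pairs (ratio of averages).

    Convenience for run logs; uses sample allele frequencies with the
    standard small-sample correction of the within-population term.
    """
    breeds = gm.breeds
    sub = {b: gm.restrict_samples(np.asarray(gm.labels == b)) for b in breeds}
    num = den = 0.0
    for i in range(len(breeds)):
        for j in range(i + 1, len(breeds)):
            g1, g2 = sub[breeds[i]], sub[breeds[j]]
            # frequency of the dataset-level minor allele in each breed
            p1, p2 = g1.maf(), g2.maf()
            n1 = (~g1.missing).sum(axis=0) * 2.0
            n2 = (~g2.missing).sum(axis=0) * 2.0
            ok = (n1 > 1) & (n2 > 1) & ~np.isnan(p1) & ~np.isnan(p2)
            p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
            h1 = p1 * (1 - p1) * n1 / (n1 - 1)
            h2 = p2 * (1 - p2) * n2 / (n2 - 1)
            n = np.sum((p1 - p2) ** 2 - h1 / n1 - h2 / n2)
            num += n
            den += n + np.sum(h1 + h2)
    return float(num / den) if den else float("nan")


def export_fixture(gm: GenotypeMatrix, truth: TruthRecord, directory) -> dict[str, Path]:
    """Write PED/MAP + label table + truth table; round-trips losslessly.

    Returns the paths written.  Re-reading with ``gio.read_genotypes`` and
    ``encoding.encode`` reproduces ``gm.values`` and ``gm.missing``
    exactly (allele letters are canonicalised on write).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "ped": directory / "genotypes.ped",
        "map": directory / "genotypes.map",
        "labels": directory / "labels.tsv",
        "truth": directory / "truth.tsv",
    }
    gio.write_ped_map(gm, paths["ped"], paths["map"])
    gio.write_labels(gm.labels, paths["labels"])
    table = pd.DataFrame(index=truth.breed_freq.index)
    table["ancestral_freq"] = truth.ancestral_freq
    table["dup_group"] = truth.dup_group
    for breed in truth.breed_freq.columns:
        table[f"freq_{breed}"] = truth.breed_freq[breed]
    table.to_csv(paths["truth"], sep="\t", float_format="%.10g")
    return paths
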