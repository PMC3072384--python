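"""Simulator behaviour: drift model, missingness, redundancy, export."""

import hashlib

import numpy as np
import pytest

from breedtrace import BreedTreeSpec, encode, export_fixture, filter_missing, simulate_dataset, two_level_spec
from breedtrace.gio import read_genotypes, read_labels
from breedtrace.simulate import SpecError, validate_spec

from oracles import weir_cockerham_fst


def flat_spec(fst, n_per_breed=50, n_snps=2000, seed=0, **kw):
    return BreedTreeSpec(
        nodes={"b1": None, "b2": None},
        branch_fst=fst,
        n_per_breed=n_per_breed,
        n_snps=n_snps,
        missing_rate=kw.pop("missing_rate", 0.0),
        redundancy_factor=kw.pop("redundancy_factor", 1),
        seed=seed,
        **kw,
    )


def test_seed_determinism():
    spec = two_level_spec(seed=7, n_per_breed=5, n_snps=100)
    gm1, t1 = simulate_dataset(spec)
    gm2, t2 = simulate_dataset(spec)
    assert np.array_equal(gm1.values, gm2.values)
    assert np.array_equal(gm1.missing, gm2.missing)
    assert t1.breed_freq.equals(t2.breed_freq)


def test_no_drift_limit_gives_near_zero_fst():
    gm, _ = simulate_dataset(flat_spec(1e-6, seed=3))
    fst = weir_cockerham_fst(gm.values, gm.missing, gm.labels.to_numpy())
    assert abs(fst) < 0.01


def test_two_breed_fst_recovers_drift_parameter():
    """F = 0.15 between two breeds: multi-SNP WC estimate lands in [0.10, 0.20]."""
    gm, _ = simulate_dataset(flat_spec(0.15, seed=5))
    fst = weir_cockerham_fst(gm.values, gm.missing, gm.labels.to_numpy())
    assert 0.10 <= fst <= 0.20


def test_balding_nichols_frequency_variance():
    """Across many breeds, Var(p_breed) ≈ F·p(1−p) per SNP (3 SE over SNPs)."""
    f = 0.1
    spec = BreedTreeSpec(
        nodes={f"b{i}": None for i in range(20)}, branch_fst=f, n_per_breed=1, n_snps=3000,
        missing_rate=0.0, redundancy_factor=1, seed=9,
    )
    _, truth = simulate_dataset(spec)
    p0 = truth.ancestral_freq.to_numpy()
    freqs = truth.breed_freq.to_numpy()
    ratio = freqs.var(axis=1, ddof=1) / (p0 * (1 - p0))
    se = ratio.std(ddof=1) / np.sqrt(len(ratio))
    assert abs(ratio.mean() - f) < 3 * se + 0.01  # clamping biases slightly low


def test_missing_rate_within_binomial_error():
    rate = 0.08
    spec = two_level_spec(seed=2, n_per_breed=20, n_snps=500, missing_rate=rate)
    gm, _ = simulate_dataset(spec)
    n = gm.missing.size
    se = np.sqrt(rate * (1 - rate) / n)
    assert abs(gm.missing.mean() - rate) < 3 * se


def test_exact_duplicates_when_flip_prob_zero():
    spec = two_level_spec(seed=4, n_per_breed=10, n_snps=200, missing_rate=0.0,
                          redundancy_flip_prob=0.0, redundancy_factor=2)
    gm, truth = simulate_dataset(spec)
    groups = truth.dup_group.groupby(truth.dup_group).groups
    checked = 0
    snp_pos = {s: i for i, s in enumerate(gm.snp_ids)}
    for base, members in groups.items():
        if len(members) > 1:
            cols = [snp_pos[s] for s in members]
            ref = gm.values[:, cols[0]]
            for c in cols[1:]:
                assert np.array_equal(gm.values[:, c], ref)
            checked += 1
    assert checked > 0


def test_duplicate_group_bookkeeping():
    spec = two_level_spec(seed=4, n_per_breed=5, n_snps=100, redundancy_factor=3)
    gm, truth = simulate_dataset(spec)
    assert set(truth.dup_group.index) == set(gm.snp_ids)
    # every duplicate maps to exactly one existing base SNP
    assert truth.dup_group.isin(gm.snp_ids).all()
    n_dup = int(round(spec.redundancy_fraction * spec.n_snps))
    assert gm.n_snps == spec.n_snps + n_dup * (spec.redundancy_factor - 1)


@pytest.mark.parametrize(
    "field,value",
    [
        ("branch_fst", 0.0),
        ("branch_fst", 1.0),
        ("n_per_breed", 0),
        ("missing_rate", 1.0),
        ("redundancy_flip_prob", 0.5),
        ("redundancy_factor", 0),
        ("ancestral_freq_range", (0.5, 0.5)),
    ],
)
def test_invalid_spec_names_offending_field(field, value):
    kw = dict(nodes={"a": None, "b": None}, branch_fst=0.1)
    kw[field] = value
    with pytest.raises(SpecError, match=field.split("_")[0]):
        validate_spec(BreedTreeSpec(**kw))


def test_export_round_trip(tmp_path, small_sim):
    gm, truth = small_sim
    paths = export_fixture(gm, truth, tmp_path)
    raw = read_genotypes(paths["ped"], paths["map"])
    labels = read_labels(paths["labels"], raw.sample_ids)
    gm2 = encode(raw, labels)
    assert np.array_equal(gm2.values, gm.values)
    assert np.array_equal(gm2.missing, gm.missing)
    assert list(gm2.sample_ids) == list(gm.sample_ids)
    assert gm2.labels.equals(gm.labels)


def test_export_empty_dataset(tmp_path):
    spec = BreedTreeSpec(nodes={"a": None, "b": None}, branch_fst=0.2, n_per_breed=2,
                         n_snps=0, missing_rate=0.0, seed=1)
    gm, truth = simulate_dataset(spec)
    paths = export_fixture(gm, truth, tmp_path)
    raw = read_genotypes(paths["ped"], paths["map"])
    assert len(raw.snp_ids) == 0 and len(raw.sample_ids) == 4


def test_export_checksum_stable_across_runs(tmp_path):
    spec = two_level_spec(seed=13, n_per_breed=5, n_snps=80)
    digests = []
    for run in ("a", "b"):
        gm, truth = simulate_dataset(spec)
        paths = export_fixture(gm, truth, tmp_path / run)
        digests.append(hashlib.sha256(paths["ped"].read_bytes()).hexdigest())
    assert digests[0] == digests[1]


def test_monomorphic_columns_survive_until_qc():
    """Fixed SNPs may arise in genotypes; QC (not the simulator) removes them."""
    spec = flat_spec(0.3, n_per_breed=5, n_snps=300, seed=6,
                     ancestral_freq_range=(0.02, 0.2))
    gm, _ = simulate_dataset(spec)
    vmax = np.where(gm.missing, -1, gm.values).max(axis=0)
    vmin = np.where(gm.missing, 3, gm.values).min(axis=0)
    mono = (vmax == vmin).sum()
    filtered = filter_missing(gm)
    assert filtered.n_snps == gm.n_snps - mono
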