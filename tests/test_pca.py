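"""PCA engine: SVD fits, out-of-sample projection, significant-PC choice."""

import numpy as np
import pytest

from breedtrace import BreedTreeSpec, choose_num_pcs, filter_missing, fit_pca, project, simulate_dataset
from breedtrace.encoding import center_impute
from breedtrace.pca import PCBasis, loo_knn_accuracy

from conftest import rng_matrix


def fit(X, k):
    m = X.shape[1]
    return fit_pca(X, k, [f"m{j}" for j in range(m)], np.zeros(m))


def test_rank_one_matrix_single_positive_singular_value():
    u = np.array([1.0, -1.0, 2.0, 0.5])
    v = np.random.default_rng(0).normal(size=6)
    X = np.outer(u - u.mean(), v)
    basis, coords = fit(X, 1)
    assert basis.sigma[0] > 0
    # coordinates collinear with u - mean(u)
    c = coords.coords[:, 0]
    assert abs(abs(np.corrcoef(c, u - u.mean())[0, 1]) - 1) < 1e-12


@pytest.mark.parametrize("k", [1, 3, 7])
def test_residual_equals_tail_spectrum(k):
    """‖A − A V_k V_kᵀ‖_F² equals the sum of squared discarded singular values."""
    for seed in range(5):
        X = rng_matrix(seed)
        basis, _ = fit(X, k)
        resid = np.linalg.norm(X - X @ basis.V @ basis.V.T) ** 2
        s = np.linalg.svd(X, compute_uv=False)
        assert resid == pytest.approx((s[k:] ** 2).sum(), rel=1e-8)


def test_basis_orthonormal():
    X = rng_matrix(3)
    basis, _ = fit(X, 5)
    gram = basis.V.T @ basis.V
    assert np.abs(gram - np.eye(5)).max() < 1e-8


def test_projection_reproduces_training_coordinates(small_sim):
    gm, _ = small_sim
    gm = filter_missing(gm)
    X, means = center_impute(gm)
    basis, coords = fit_pca(X, 3, gm.snp_ids, means, gm.sample_ids)
    got = project(basis, gm.values[7], gm.missing[7], gm.snp_ids)
    assert np.abs(got - coords.coords[7]).max() < 1e-8


def test_all_missing_sample_projects_to_origin(small_sim):
    gm, _ = small_sim
    gm = filter_missing(gm)
    X, means = center_impute(gm)
    basis, _ = fit_pca(X, 2, gm.snp_ids, means)
    coord = project(basis, np.zeros(gm.n_snps), np.ones(gm.n_snps, dtype=bool), gm.snp_ids)
    assert np.abs(coord).max() == 0.0


def test_projection_invariant_to_snp_order(small_sim):
    gm, _ = small_sim
    gm = filter_missing(gm)
    X, means = center_impute(gm)
    basis, _ = fit_pca(X, 2, gm.snp_ids, means)
    perm = np.random.default_rng(0).permutation(gm.n_snps)
    a = project(basis, gm.values[0], gm.missing[0], gm.snp_ids)
    b = project(basis, gm.values[0][perm], gm.missing[0][perm], gm.snp_ids[perm])
    assert np.allclose(a, b)


def test_projection_missing_snp_listed():
    X = rng_matrix(0, 5, 4)
    basis, _ = fit_pca(X, 1, ["m0", "m1", "m2", "m3"], np.zeros(4))
    with pytest.raises(KeyError, match="m3"):
        project(basis, np.zeros(3), np.zeros(3, dtype=bool), ["m0", "m1", "m2"])


def test_k_above_rank_rejected():
    X = np.outer([1.0, -1.0], np.ones(5))
    with pytest.raises(ValueError, match="rank"):
        fit(X, 2)


def test_out_of_sample_individual_lands_near_its_breed():
    """Held-out individuals sit closer to their own breed centroid in PC space."""
    spec = BreedTreeSpec(nodes={"p": None, "q": None}, branch_fst=0.3, n_per_breed=21,
                         n_snps=400, missing_rate=0.02, seed=8)
    gm, _ = simulate_dataset(spec)
    gm = filter_missing(gm)
    holdout = np.array([0, 21])
    train = np.setdiff1d(np.arange(gm.n_samples), holdout)
    gtrain = gm.restrict_samples(train)
    gtrain = filter_missing(gtrain)
    X, means = center_impute(gtrain)
    basis, coords = fit_pca(X, 2, gtrain.snp_ids, means, gtrain.sample_ids)
    cent = {b: coords.coords[gtrain.labels.to_numpy() == b].mean(axis=0) for b in gtrain.breeds}
    for i in holdout:
        c = project(basis, gm.values[i], gm.missing[i], gm.snp_ids)
        own = gm.labels.iloc[i]
        d_own = np.linalg.norm(c - cent[own])
        d_other = min(np.linalg.norm(c - cent[b]) for b in gtrain.breeds if b != own)
        assert d_own < d_other


def test_separated_breeds_disjoint_on_pc1():
    gm, _ = simulate_dataset(BreedTreeSpec(nodes={"p": None, "q": None}, branch_fst=0.3,
                                           n_per_breed=25, n_snps=500, missing_rate=0.0, seed=2))
    gm = filter_missing(gm)
    X, means = center_impute(gm)
    _, coords = fit_pca(X, 1, gm.snp_ids, means, gm.sample_ids)
    pc1 = coords.coords[:, 0]
    lab = gm.labels.to_numpy()
    a, b = pc1[lab == "p"], pc1[lab == "q"]
    assert a.max() < b.min() or b.max() < a.min()


def test_choose_num_pcs_planted_rank_one_axis():
    """Three collinear, well-separated breeds: one PC suffices and is chosen."""
    rng = np.random.default_rng(5)
    direction = rng.normal(size=40)
    direction /= np.linalg.norm(direction)
    rows, labels = [], []
    for c, b in zip((-10.0, 0.0, 10.0), ("a", "b", "c")):
        rows.append(c * direction + 0.1 * rng.normal(size=(15, 40)))
        labels += [b] * 15
    X = np.vstack(rows)
    X -= X.mean(axis=0)
    assert choose_num_pcs(X, labels, [1, 2, 3]) == 1


def test_choose_num_pcs_singleton_candidate():
    X = rng_matrix(1, 12, 20)
    labels = ["a"] * 6 + ["b"] * 6
    assert choose_num_pcs(X, labels, [1]) == 1


def test_sign_flips_do_not_change_votes(small_sim):
    gm, _ = small_sim
    gm = filter_missing(gm)
    X, means = center_impute(gm)
    basis, _ = fit_pca(X, 3, gm.snp_ids, means, gm.sample_ids)
    flipped = PCBasis(V=basis.V * np.array([1, -1, -1]), sigma=basis.sigma,
                      column_means=basis.column_means, snp_ids=basis.snp_ids)
    lab = gm.labels.to_numpy(dtype=str)
    for b in (basis, flipped):
        coords = (X @ b.V)
        acc = loo_knn_accuracy(coords, lab, gm.sample_ids)
        test = project(b, gm.values[3], gm.missing[3], gm.snp_ids)
        d = np.linalg.norm(coords - test, axis=1)
        if b is basis:
            ref = (acc, np.sort(d)[:5])
        else:
            assert acc == ref[0]
            assert np.allclose(np.sort(d)[:5], ref[1])
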