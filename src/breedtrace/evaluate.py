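"""Complete leave-one-out cross-validation of the breed-assignment pipeline.

Each individual in turn is held out; every decision-tree node on its
root-to-leaf reference path is refit on the remaining individuals — PCA,
candidate ranking, and redundancy-removed panels are all recomputed from
the training set only, with the tree topology and per-node significant-PC
counts held fixed — and the held-out individual is then voted on at each
node in each requested marker mode.  Two statistics are accumulated per
node, mode, and breed:

* classification accuracy A — the percentage of individuals whose
  predicted child group at the node contains their reference breed
  (an "unassigned" vote counts as incorrect);
* average correct neighbours N̄ — the mean number, out of five, of
  nearest neighbours belonging to the individual's reference breed.

Per-node denominators are the individuals whose reference breed belongs
to the node, so every individual contributes one decision at every node
of its reference path regardless of earlier decisions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._voting import majority_label, neighbor_order
from .encoding import GenotypeMatrix
from .pca import _svd, numerical_rank
from .selection import SnpScoreTable, cssp_select, top_candidates
from .tree import CANDIDATE_MODE, FULL_MODE, TIER_MODES, TreeConfig, TreeNode, build_tree

_VALID_MODES = (FULL_MODE, CANDIDATE_MODE) + TIER_MODES


@dataclass
class EvalReport:
    """Per-decision LOOCV records plus aggregation helpers.

    ``records`` has one row per (sample, path node, mode, neighbour
    count): the predicted child, correctness, and the correct-neighbour
    count of the vote.
    """

    records: pd.DataFrame
    modes: tuple[str, ...]
    n_neighbors: int

    def node_summary(self) -> pd.DataFrame:
        """Accuracy (%), N̄, and unassigned counts per (node, mode, n_neighbors)."""
        g = self.records.groupby(["node", "mode", "n_neighbors"], sort=True)
        out = g.agg(
            n=("correct", "size"),
            n_correct=("correct", "sum"),
            mean_correct_neighbors=("n_correct_breed", "mean"),
            n_unassigned=("unassigned", "sum"),
        ).reset_index()
        out["accuracy_pct"] = 100.0 * out["n_correct"] / out["n"]
        return out

    def breed_summary(self) -> pd.DataFrame:
        """Per-(breed, node, mode) assigned-correct fraction and N̄."""
        g = self.records.groupby(["breed", "node", "edge", "mode", "n_neighbors"], sort=True)
        out = g.agg(
            n=("correct", "size"),
            n_correct=("correct", "sum"),
            mean_correct_neighbors=("n_correct_breed", "mean"),
        ).reset_index()
        out["frac_correct"] = out["n_correct"] / out["n"]
        return out

    def accuracy(self, node: str, mode: str, n_neighbors: int | None = None) -> float:
        """Classification accuracy (%) at a node in a mode."""
        nn = self.n_neighbors if n_neighbors is None else n_neighbors
        r = self.records
        sel = r[(r["node"] == node) & (r["mode"] == mode) & (r["n_neighbors"] == nn)]
        if sel.empty:
            raise KeyError(f"no records for node={node!r} mode={mode!r} n_neighbors={nn}")
        return 100.0 * sel["correct"].mean()

    def mean_correct_neighbors(self, node: str, mode: str, n_neighbors: int | None = None) -> float:
        nn = self.n_neighbors if n_neighbors is None else n_neighbors
        r = self.records
        sel = r[(r["node"] == node) & (r["mode"] == mode) & (r["n_neighbors"] == nn)]
        if sel.empty:
            raise KeyError(f"no records for node={node!r} mode={mode!r} n_neighbors={nn}")
        return float(sel["n_correct_breed"].mean())

    def overall_accuracy(self, mode: str, n_neighbors: int | None = None) -> float:
        """Percentage of individuals correct at every node of their path."""
        nn = self.n_neighbors if n_neighbors is None else n_neighbors
        r = self.records
        sel = r[(r["mode"] == mode) & (r["n_neighbors"] == nn)]
        per_sample = sel.groupby("sample")["correct"].all()
        return 100.0 * per_sample.mean()

    def to_json_dict(self) -> dict:
        return {
            "modes": list(self.modes),
            "n_neighbors": self.n_neighbors,
            "node_summary": self.node_summary().to_dict(orient="records"),
            "breed_summary": self.breed_summary().to_dict(orient="records"),
            "overall_accuracy_pct": {m: self.overall_accuracy(m) for m in self.modes},
        }


def _prepare_training(vals: np.ndarray, miss: np.ndarray):
    """Drop unusable columns, mean-impute, centre.  Returns (X, means, keep)."""
    called = (~miss).sum(axis=0)
    vmax = np.where(miss, -1, vals).max(axis=0)
    vmin = np.where(miss, 3, vals).min(axis=0)
    keep = (called > 0) & (vmax > vmin)
    v = vals[:, keep].astype(np.float64)
    mk = miss[:, keep]
    means = np.where(mk, 0.0, v).sum(axis=0) / (~mk).sum(axis=0)
    X = np.where(mk, means[None, :], v) - means[None, :]
    return X, means, np.flatnonzero(keep)


def _vote(coord, coords, ids, child_labels, breed_labels, breed, nn):
    d = np.sqrt(((coords - coord[None, :]) ** 2).sum(axis=1))
    order = neighbor_order(d, ids)
    top = order[: min(nn, len(order))]
    predicted = majority_label(child_labels[top])
    return (
        predicted if predicted is not None else "unassigned",
        int((breed_labels[top] == breed).sum()),
    )


def loocv(
    gm: GenotypeMatrix,
    config: TreeConfig,
    modes: Sequence[str] = (FULL_MODE, "P1", "P2", "P3"),
    n_neighbors: int = 5,
    neighbor_grid: Sequence[int] | None = None,
    root_only: bool = False,
) -> EvalReport:
    """Run the full leave-one-out experiment.

    ``neighbor_grid`` additionally records full-SNP votes at each listed
    neighbour count (used to probe robustness of the majority rule);
    ``root_only`` restricts the evaluation to the root node.
    """
    modes = tuple(modes)
    for m in modes:
        if m not in _VALID_MODES:
            raise ValueError(f"unknown mode {m!r}; valid: {_VALID_MODES}")
    counts = gm.labels.value_counts()
    if (counts < 2).any():
        lone = counts[counts < 2].index.tolist()
        raise ValueError(f"every breed needs >= 2 individuals for LOOCV; offending: {lone}")

    ref_tree = build_tree(gm, replace(config, build_panels=False))
    panel_modes = [m for m in modes if m in TIER_MODES]
    need_candidates = bool(panel_modes) or CANDIDATE_MODE in modes

    # per-internal-node training data cache
    node_data: dict[str, dict] = {}
    for node in ref_tree.iter_nodes():
        if node.is_leaf:
            continue
        mask = np.asarray(gm.labels.isin(node.breeds))
        sub_vals = gm.values[mask]
        sub_miss = gm.missing[mask]
        ids = gm.sample_ids[mask]
        breeds_arr = gm.labels.to_numpy(dtype=str)[mask]
        node_data[node.name] = {
            "vals": sub_vals,
            "miss": sub_miss,
            "ids": ids,
            "breeds": breeds_arr,
            "child": np.array([node.child_of_breed[b] for b in breeds_arr], dtype=str),
            "row": {s: i for i, s in enumerate(ids)},
            "k": node.k,
            "node": node,
            "snp_ids": gm.snp_ids,
        }

    grid = sorted(set(neighbor_grid or []))
    records: list[dict] = []
    for sample, breed in gm.labels.items():
        path = ref_tree.path_for_breed(breed)
        if root_only:
            path = path[:1]
        for node in path:
            nd = node_data[node.name]
            i = nd["row"][sample]
            train = np.arange(len(nd["ids"])) != i
            X, means, keep = _prepare_training(nd["vals"][train], nd["miss"][train])
            kept_ids = nd["snp_ids"][keep]
            U, s, Vt = _svd(X)
            k = min(nd["k"], numerical_rank(s))
            coords_full = U[:, :k] * s[:k][None, :]
            tv = nd["vals"][i, keep].astype(np.float64)
            tm = nd["miss"][i, keep]
            x = np.where(tm, means, tv) - means
            test_full = x @ Vt[:k].T

            correct_child = node.child_of_breed[breed]
            t_ids = nd["ids"][train]
            t_breeds = nd["breeds"][train]
            t_child = nd["child"][train]

            def emit(mode, coord, coords, nn):
                predicted, n_corr = _vote(coord, coords, t_ids, t_child, t_breeds, breed, nn)
                records.append(
                    {
                        "sample": sample,
                        "breed": breed,
                        "node": node.name,
                        "edge": f"{node.name} -> {correct_child}",
                        "mode": mode,
                        "n_neighbors": nn,
                        "predicted": predicted,
                        "correct": predicted == correct_child,
                        "unassigned": predicted == "unassigned",
                        "n_correct_breed": n_corr,
                    }
                )

            if FULL_MODE in modes:
                emit(FULL_MODE, test_full, coords_full, n_neighbors)
                for nn in grid:
                    if nn != n_neighbors:
                        emit(FULL_MODE, test_full, coords_full, nn)

            if need_candidates:
                scores = SnpScoreTable(kept_ids, np.einsum("ij,ij->j", Vt[:k], Vt[:k]), k)
                n_top = min(config.resolve_n_top(len(kept_ids)), len(kept_ids))
                cand_ids = top_candidates(scores, n_top)
                pos = {sid: j for j, sid in enumerate(kept_ids)}
                cand_idx = np.array([pos[sid] for sid in cand_ids], dtype=int)

                if CANDIDATE_MODE in modes:
                    emit(
                        CANDIDATE_MODE,
                        *_subset_projection(X, means, cand_idx, k, tv, tm),
                        n_neighbors,
                    )

                if panel_modes:
                    p1 = config.resolve_p1(node.name)
                    tiers = config.tier_sizes or (p1, 2 * p1, 3 * p1)
                    c = min(tiers[2], len(cand_ids))
                    order_ids = cssp_select(X[:, cand_idx], cand_ids, k, c)
                    order_idx = np.array([pos[sid] for sid in order_ids], dtype=int)
                    tier_size = dict(zip(TIER_MODES, tiers))
                    for mode in panel_modes:
                        sub_idx = order_idx[: min(tier_size[mode], len(order_idx))]
                        emit(mode, *_subset_projection(X, means, sub_idx, k, tv, tm), n_neighbors)

    df = pd.DataFrame.from_records(records)
    return EvalReport(records=df, modes=modes, n_neighbors=n_neighbors)


def _subset_projection(X, means, idx, k, test_vals, test_miss):
    """Refit PCA on a column subset and project the held-out sample."""
    Xs = X[:, idx]
    _, s, Vt = _svd(Xs)
    k_eff = min(k, numerical_rank(s))
    V = Vt[:k_eff].T
    coords = Xs @ V
    x = np.where(test_miss[idx], means[idx], test_vals[idx]) - means[idx]
    return x @ V, coords


def report_tables(report: EvalReport, directory) -> dict[str, Path]:
    """Write the evaluation report as TSV tables plus a JSON document.

    ``node_summary.tsv`` holds per-node accuracies and neighbour counts
    (2 decimals); ``report.json`` carries full precision; one TSV per
    breed lays out its reference path edge by edge with per-mode A and N̄
    columns.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    node_df = report.node_summary().copy()
    node_df["accuracy_pct"] = node_df["accuracy_pct"].round(2)
    node_df["mean_correct_neighbors"] = node_df["mean_correct_neighbors"].round(2)
    paths["node_summary"] = directory / "node_summary.tsv"
    node_df.to_csv(paths["node_summary"], sep="\t", index=False)

    paths["json"] = directory / "report.json"
    with open(paths["json"], "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=1, default=float)

    breed_dir = directory / "breed_tables"
    breed_dir.mkdir(exist_ok=True)
    bs = report.breed_summary()
    bs = bs[bs["n_neighbors"] == report.n_neighbors]
    for breed, sub in bs.groupby("breed"):
        wide = sub.pivot_table(
            index="edge",
            columns="mode",
            values=["frac_correct", "mean_correct_neighbors"],
            sort=False,
        )
        wide.columns = [f"{mode}_{'A' if stat == 'frac_correct' else 'Nbar'}" for stat, mode in wide.columns]
        wide = wide.round(2)
        p = breed_dir / f"{str(breed).replace(' ', '_')}.tsv"
        wide.to_csv(p, sep="\t")
        paths[f"breed:{breed}"] = p
    return paths
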